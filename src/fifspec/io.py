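"""Reading and writing the package's file formats.

Images are single-plane grayscale TIFFs (8- or 16-bit) with the pixel size
supplied either by a JSON sidecar (``<image>.json`` holding at least
``pixel_size_um``) or explicitly by the caller — intensities are never
rescaled. RoIs are JSON lists of named polygons with vertices in 0-based
pixel-corner coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .models import ConfocalImage, GroundTruthManifest

__all__ = ["read_image", "write_image", "read_rois", "write_rois", "sidecar_path"]


def sidecar_path(image_path) -> Path:
    return Path(str(image_path) + ".json")


def read_image(path, pixel_size_um: float | None = None) -> ConfocalImage:
    """Load a grayscale TIFF as a :class:`ConfocalImage`.

    The pixel size comes from ``pixel_size_um`` if given, otherwise from the
    sidecar JSON; a missing pixel size is an error (areas in µm² would be
    undefined). RGB and floating-point TIFFs are rejected.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-plane grayscale image, got shape {data.shape} "
            "(RGB/multi-channel TIFFs are not supported)"
        )
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path.name}: expected an 8/16-bit integer TIFF, got dtype {data.dtype}")
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if pixel_size_um is None:
        raise ValueError(
            f"{path.name}: pixel size unknown — provide pixel_size_um or a sidecar "
            f"{sc.name} with a 'pixel_size_um' entry"
        )
    return ConfocalImage(data, float(pixel_size_um), meta=meta)


def write_image(image: ConfocalImage, path, manifest: GroundTruthManifest | None = None) -> None:
    """Write a 16-bit TIFF plus a JSON sidecar (pixel size and, if given,
    the full ground-truth manifest)."""
    path = Path(path)
    data = np.asarray(image.data)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("image data must be integer for TIFF export")
    tifffile.imwrite(path, data.astype(np.uint16))
    sidecar = {"pixel_size_um": image.pixel_size_um}
    sidecar.update({k: v for k, v in image.meta.items() if _json_safe(v)})
    if manifest is not None:
        sidecar["manifest"] = manifest.to_dict()
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments (shared endpoints ignored)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _is_simple_polygon(v: np.ndarray) -> bool:
    n = len(v)
    for i in range(n):
        a1, a2 = v[i], v[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(a1, a2, v[j], v[(j + 1) % n]):
                return False
    return True


def read_rois(path) -> list[tuple[str, np.ndarray]]:
    """Load named RoI polygons from JSON.

    Schema: ``[{"name": str, "vertices": [[x, y], ...]}, ...]`` with
    vertices in 0-based pixel coordinates. Polygons with fewer than three
    vertices, duplicate names, or self-intersections are rejected with the
    RoI named in the error.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("RoI file must contain a JSON list of {name, vertices} objects")
    out: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    for i, item in enumerate(raw):
        name = item.get("name", f"roi_{i}")
        if name in seen:
            raise ValueError(f"duplicate RoI name {name!r}")
        seen.add(name)
        v = np.asarray(item["vertices"], dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"RoI {name!r}: a polygon needs at least 3 [x, y] vertices")
        if not _is_simple_polygon(v):
            raise ValueError(f"RoI {name!r}: polygon is self-intersecting")
        out.append((name, v))
    return out


def write_rois(rois: list[tuple[str, np.ndarray]], path) -> None:
    payload = [
        {"name": name, "vertices": np.asarray(v, dtype=float).tolist()} for name, v in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
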