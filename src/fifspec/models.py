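"""Core domain types shared across the simulation and analysis modules.

Units convention: lengths in micrometres (µm), surface densities in
molecules (or protomers) per µm², intensities in raw detector units (a.u.).
Oligomer sizes count protomers (subunits), so a dimer at oligomer density
C contributes 2·C protomers/µm².
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Calibration constants of the reference imaging configuration: a confocal
# beam waist measured with sub-resolution beads, the monomeric brightness of
# the mEGFP standard and the beam shape factor for a thin layer / 1-AU pinhole.
DEFAULT_W_XY_UM = 0.2656
DEFAULT_PIXEL_SIZE_UM = 0.06
DEFAULT_Q0 = 205.0
DEFAULT_GAMMA = 0.5
DEFAULT_QB_REFERENCE = 113.5

PSF_FORMS = ("gaussian_2d", "gaussian_3d", "flat_disk")
GEOMETRY_KINDS = ("thin_layer_focal_plane", "membrane_axial_cross_section", "solution_3d")


@dataclass(frozen=True)
class PSFModel:
    """Illumination point-spread function.

    Parameters
    ----------
    w_xy:
        Lateral 1/e² Gaussian beam waist in µm. The lateral profile is
        ``exp(-2 r² / w_xy²)`` with unit peak.
    w_z:
        Optional axial 1/e² extent in µm (3-D Gaussian form).
    form:
        One of ``gaussian_2d``, ``gaussian_3d`` or ``flat_disk``.
    """

    w_xy: float = DEFAULT_W_XY_UM
    w_z: float | None = None
    form: str = "gaussian_2d"

    def __post_init__(self) -> None:
        if self.w_xy <= 0:
            raise ValueError(f"lateral waist must be positive, got {self.w_xy}")
        if self.w_z is not None and self.w_z <= 0:
            raise ValueError(f"axial waist must be positive, got {self.w_z}")
        if self.form not in PSF_FORMS:
            raise ValueError(f"unknown PSF form {self.form!r}; expected one of {PSF_FORMS}")

    @property
    def area_um2(self) -> float:
        """Area integral of the lateral PSF, (1/2)·π·w_xy² (µm²)."""
        return 0.5 * np.pi * self.w_xy**2

    @property
    def squared_area_um2(self) -> float:
        """Area integral of the squared lateral PSF, (1/4)·π·w_xy² (µm²)."""
        return 0.25 * np.pi * self.w_xy**2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SampleGeometry:
    """Geometry of the sample region contributing detected signal.

    ``kind`` selects between a thin fluorophore layer in the focal plane,
    a membrane imaged in axial cross-section (plane containing the optical
    axis), and a full 3-D solution. Optical parameters are only required
    for the cross-section case, where the pinhole bounds the detected
    region.
    """

    kind: str = "thin_layer_focal_plane"
    layer_thickness_um: float = 0.0
    pinhole_um: float | None = None
    refractive_index: float = 1.518
    numerical_aperture: float = 1.4
    lambda_ex_um: float = 0.488
    lambda_em_um: float = 0.555

    def __post_init__(self) -> None:
        if self.kind not in GEOMETRY_KINDS:
            raise ValueError(f"unknown geometry kind {self.kind!r}; expected one of {GEOMETRY_KINDS}")
        if self.numerical_aperture >= self.refractive_index:
            raise ValueError("numerical aperture must be smaller than the medium refractive index")
        for name in ("refractive_index", "numerical_aperture", "lambda_ex_um", "lambda_em_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pinhole_um is not None and self.pinhole_um <= 0:
            raise ValueError("pinhole diameter must be positive")


@dataclass(frozen=True)
class DetectorModel:
    """Additive detector model: constant offset, Gaussian read noise and a
    Gaussian autofluorescence background.

    ``shot_noise_gain`` optionally adds a signal-proportional variance term
    (variance = gain · expected photo-signal), off by default.
    """

    offset: float = 100.0
    read_noise_sd: float = 20.0
    background_mean: float = 100.0
    background_sd: float = 20.0
    shot_noise_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read-noise SD must be non-negative")
        if self.background_sd < 0:
            raise ValueError("background SD must be non-negative")
        if self.shot_noise_gain < 0:
            raise ValueError("shot-noise gain must be non-negative")

    @property
    def baseline(self) -> float:
        """Expected pixel value in the absence of molecules."""
        return self.offset + self.background_mean

    @property
    def noise_variance(self) -> float:
        """Signal-independent pixel variance (read noise + background)."""
        return self.read_noise_sd**2 + self.background_sd**2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SpeciesMixture:
    """Surface mixture of oligomeric species.

    ``species`` is a sequence of ``(m, C_m)`` pairs: oligomer size in
    protomers and oligomer surface density in oligomers/µm². ``q0`` is the
    per-protomer brightness in a.u. at the beam centre.
    """

    species: tuple[tuple[int, float], ...]
    q0: float = DEFAULT_Q0

    def __init__(self, species: Sequence[tuple[int, float]], q0: float = DEFAULT_Q0):
        species = tuple((int(m), float(c)) for m, c in species)
        if not species:
            raise ValueError("mixture needs at least one species")
        for m, c in species:
            if m < 1:
                raise ValueError(f"oligomer size must be >= 1, got {m}")
            if c < 0:
                raise ValueError(f"surface density must be >= 0, got {c}")
        if q0 <= 0:
            raise ValueError("protomer brightness q0 must be positive")
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "q0", float(q0))

    @property
    def total_protomer_density(self) -> float:
        """Σ m·C_m, protomers/µm²."""
        return float(sum(m * c for m, c in self.species))

    @property
    def total_oligomer_density(self) -> float:
        """Σ C_m, oligomers/µm²."""
        return float(sum(c for _, c in self.species))

    @property
    def protomer_fractions(self) -> dict[int, float]:
        """Protomer mole fraction per oligomer size."""
        tot = self.total_protomer_density
        if tot == 0:
            return {m: 0.0 for m, _ in self.species}
        return {m: m * c / tot for m, c in self.species}

    @classmethod
    def pure(cls, m: int, protomer_density: float, q0: float = DEFAULT_Q0) -> "SpeciesMixture":
        """Single n-mer species at the given *protomer* density."""
        return cls([(m, protomer_density / m)], q0=q0)

    @classmethod
    def from_protomer_fractions(
        cls,
        total_protomer_density: float,
        fractions: dict[int, float],
        q0: float = DEFAULT_Q0,
    ) -> "SpeciesMixture":
        """Build a mixture from protomer mole fractions summing to 1."""
        s = sum(fractions.values())
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"protomer fractions must sum to 1, got {s}")
        species = [(m, f * total_protomer_density / m) for m, f in fractions.items() if f > 0]
        return cls(species, q0=q0)

    def to_dict(self) -> dict:
        return {"species": [list(s) for s in self.species], "q0": self.q0}


@dataclass(frozen=True)
class PunctaSpec:
    """High-intensity punctae mimicking endocytic vesicles: 2-D Gaussian
    blobs at Poisson-random locations, peak amplitude ``intensity_scale``
    times the local image median."""

    count_density: float = 0.05
    intensity_scale: float = 10.0
    radius_um: float = 0.3

    def __post_init__(self) -> None:
        for name in ("count_density", "intensity_scale", "radius_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ConfocalImage:
    """Single-plane grayscale confocal image: detector counts plus the pixel
    size needed to convert areas to µm²."""

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class GroundTruthManifest:
    """Everything needed to reproduce a simulated image bit-identically and
    to score downstream estimates against the truth."""

    mixture: SpeciesMixture
    detector: DetectorModel
    psf: PSFModel
    seed: int
    pixel_size_um: float
    shape_px: tuple[int, int]
    pad_um: float = 0.0
    molecule_counts: dict[int, int] = field(default_factory=dict)
    saturation_fraction: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def total_protomers(self) -> int:
        return int(sum(m * n for m, n in self.molecule_counts.items()))

    def to_dict(self) -> dict:
        return {
            "mixture": self.mixture.to_dict(),
            "detector": self.detector.to_dict(),
            "psf": self.psf.to_dict(),
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
            "shape_px": list(self.shape_px),
            "pad_um": self.pad_um,
            "molecule_counts": {str(k): v for k, v in self.molecule_counts.items()},
            "saturation_fraction": self.saturation_fraction,
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(
            mixture=SpeciesMixture([tuple(s) for s in d["mixture"]["species"]], q0=d["mixture"]["q0"]),
            detector=DetectorModel(**d["detector"]),
            psf=PSFModel(**d["psf"]),
            seed=d["seed"],
            pixel_size_um=d["pixel_size_um"],
            shape_px=tuple(d["shape_px"]),
            pad_um=d.get("pad_um", 0.0),
            molecule_counts={int(k): v for k, v in d.get("molecule_counts", {}).items()},
            saturation_fraction=d.get("saturation_fraction", 0.0),
            flags=list(d.get("flags", [])),
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
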