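"""Forward simulation of confocal images of membranes carrying oligomer
mixtures, with closed-form moment oracles.

Image model
-----------
Molecules of size ``m`` are scattered as a 2-D Poisson process with oligomer
density ``C_m``. A molecule at distance ``r`` from a pixel centre contributes
``m·q0·exp(-2 r²/w_xy²)`` counts (point-sampled Gaussian PSF; pixels are much
smaller than the waist so area integration over the pixel is unnecessary).
On top of the photo-signal each pixel receives a constant offset, Gaussian
read noise and a Gaussian autofluorescence background, and is finally
clipped to [0, 65535] and quantised to 16-bit integers.

Campbell's theorem gives the exact first two moments of the (pre-quantisation)
pixel distribution; :func:`closed_form_moments` is the oracle every brightness
estimator in the package is validated against:

    mean = offset + I_bg + Σ_m C_m · m·q0 · A_PSF
    var  = σ_det² + σ_bg² + Σ_m C_m · (m·q0)² · γ·A_PSF

with ``A_PSF = (1/2)π w_xy²`` and ``γ = 1/2`` (∫PSF² = γ·∫PSF for a Gaussian).
"""

from __future__ import annotations

import numpy as np

from .models import (
    ConfocalImage,
    DetectorModel,
    GroundTruthManifest,
    PSFModel,
    PunctaSpec,
    SpeciesMixture,
)

__all__ = [
    "simulate_molecule_field",
    "render_image",
    "closed_form_moments",
    "simulate_image",
    "add_punctae",
    "simulate_calibration_series",
    "simulate_patch_series",
    "CALIBRATION_DENSITY_FLOOR",
]

# Densities below ~15 protomers/µm² produce too few fluctuations per beam
# area for a reliable brightness calibration and are flagged.
CALIBRATION_DENSITY_FLOOR = 15.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_molecule_field(
    mixture: SpeciesMixture,
    width_um: float,
    height_um: float,
    seed,
) -> np.ndarray:
    """Draw molecule positions for each species of a mixture.

    Per species the molecule count is Poisson(C_m · area) and positions are
    i.i.d. uniform over the ``[0, width] × [0, height]`` field.

    Returns a float array of shape ``(N, 3)`` with columns ``x (µm)``,
    ``y (µm)``, ``m (protomers)``.
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError(f"field area must be positive, got {width_um} x {height_um} µm")
    rng = _rng(seed)
    area = width_um * height_um
    rows = []
    for m, c in mixture.species:
        n = rng.poisson(c * area)
        if n == 0:
            continue
        xy = rng.uniform([0.0, 0.0], [width_um, height_um], size=(n, 2))
        rows.append(np.column_stack([xy, np.full(n, m, dtype=float)]))
    if not rows:
        return np.empty((0, 3))
    return np.concatenate(rows, axis=0)


def render_image(
    field: np.ndarray,
    psf: PSFModel,
    detector: DetectorModel,
    pixel_size_um: float,
    shape_px: tuple[int, int],
    seed,
    q0: float | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> ConfocalImage:
    """Render a molecule field into a 16-bit confocal image.

    Pixel ``(i, j)`` (row, column) has its centre at
    ``(x, y) = origin + ((j + 0.5)·p, (i + 0.5)·p)``. Molecules outside the
    image bounds still contribute through their PSF tails.

    ``q0`` defaults to 205 a.u./protomer; pass explicitly when the field was
    not generated from a :class:`SpeciesMixture` (the field array itself
    carries only sizes, not brightnesses).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = _rng(seed)
    q0 = 205.0 if q0 is None else float(q0)
    ny, nx = int(shape_px[0]), int(shape_px[1])
    signal = np.zeros((ny, nx))

    field = np.asarray(field, dtype=float).reshape(-1, 3)
    if field.size:
        p = pixel_size_um
        w2 = psf.w_xy**2
        # stamp radius: 4 waists; the Gaussian tail beyond is < e^-32
        r_px = int(np.ceil(4.0 * psf.w_xy / p))
        xc = (np.arange(nx) + 0.5) * p + origin_um[0]
        yc = (np.arange(ny) + 0.5) * p + origin_um[1]
        for x, y, m in field:
            j0 = int(np.floor((x - origin_um[0]) / p - 0.5))
            i0 = int(np.floor((y - origin_um[1]) / p - 0.5))
            jlo, jhi = max(j0 - r_px, 0), min(j0 + r_px + 2, nx)
            ilo, ihi = max(i0 - r_px, 0), min(i0 + r_px + 2, ny)
            if jlo >= jhi or ilo >= ihi:
                continue
            dx2 = (xc[jlo:jhi] - x) ** 2
            dy2 = (yc[ilo:ihi] - y) ** 2
            signal[ilo:ihi, jlo:jhi] += (m * q0) * np.exp(
                (-2.0 / w2) * (dy2[:, None] + dx2[None, :])
            )

    values = (
        signal
        + detector.offset
        + rng.normal(0.0, detector.read_noise_sd, size=signal.shape)
        + rng.normal(detector.background_mean, detector.background_sd, size=signal.shape)
    )
    if detector.shot_noise_gain > 0:
        values = values + rng.normal(0.0, 1.0, size=signal.shape) * np.sqrt(
            detector.shot_noise_gain * np.maximum(signal, 0.0)
        )

    clipped = np.clip(np.rint(values), 0, 65535)
    saturation = float(np.mean(clipped >= 65535))
    img = ConfocalImage(
        clipped.astype(np.uint16),
        pixel_size_um=pixel_size_um,
        meta={"saturation_fraction": saturation},
    )
    return img


def closed_form_moments(
    mixture: SpeciesMixture,
    psf: PSFModel,
    detector: DetectorModel,
    pixel_size_um: float | None = None,
) -> tuple[float, float]:
    """Analytic per-pixel mean and variance of the rendered-image model.

    The pixel value is a point sample of the molecular shot-noise field, so
    the moments are independent of the pixel size (kept in the signature for
    interface symmetry with :func:`render_image`). Quantisation to integers
    is ignored (it adds < 1/12 a.u.² of variance).
    """
    a_psf = psf.area_um2
    gamma = psf.squared_area_um2 / psf.area_um2  # = 0.5 for a Gaussian
    mean = detector.baseline
    var = detector.noise_variance
    signal_mean = 0.0
    for m, c in mixture.species:
        mean += c * m * mixture.q0 * a_psf
        signal_mean += c * m * mixture.q0 * a_psf
        var += c * (m * mixture.q0) ** 2 * gamma * a_psf
    if detector.shot_noise_gain > 0:
        var += detector.shot_noise_gain * signal_mean
    return float(mean), float(var)


def simulate_image(
    mixture: SpeciesMixture,
    psf: PSFModel,
    detector: DetectorModel,
    shape_px: tuple[int, int],
    pixel_size_um: float,
    seed: int,
    pad_um: float | None = None,
) -> tuple[ConfocalImage, GroundTruthManifest]:
    """Simulate a field padded beyond the image bounds and render it.

    Padding (default 4 lateral waists) removes edge deficits: pixels near the
    border receive PSF tails from molecules just outside the imaged area, as
    they would in a real, larger sample.
    """
    if pad_um is None:
        pad_um = 4.0 * psf.w_xy
    ny, nx = int(shape_px[0]), int(shape_px[1])
    w_um = nx * pixel_size_um + 2 * pad_um
    h_um = ny * pixel_size_um + 2 * pad_um
    ss = np.random.SeedSequence(seed)
    rng_field, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    field = simulate_molecule_field(mixture, w_um, h_um, rng_field)
    img = render_image(
        field,
        psf,
        detector,
        pixel_size_um,
        shape_px,
        rng_noise,
        q0=mixture.q0,
        origin_um=(pad_um, pad_um),
    )
    sizes = sorted({m for m, _ in mixture.species})
    counts = {m: (int(np.sum(field[:, 2] == m)) if field.size else 0) for m in sizes}
    manifest = GroundTruthManifest(
        mixture=mixture,
        detector=detector,
        psf=psf,
        seed=seed,
        pixel_size_um=pixel_size_um,
        shape_px=(ny, nx),
        pad_um=pad_um,
        molecule_counts=counts,
        saturation_fraction=img.meta.get("saturation_fraction", 0.0),
    )
    return img, manifest


def add_punctae(
    image: ConfocalImage,
    spec: PunctaSpec,
    seed,
) -> tuple[ConfocalImage, np.ndarray]:
    """Contaminate an image with bright Gaussian blobs (vesicle mimics).

    Blob centres form a Poisson process at ``spec.count_density`` per µm²;
    each blob has peak amplitude ``spec.intensity_scale`` times the image
    median and Gaussian profile with σ = radius/2. Returns the contaminated
    image and the true puncta mask (pixels within one radius of a centre),
    for scoring despotting.
    """
    rng = _rng(seed)
    ny, nx = image.shape
    p = image.pixel_size_um
    area = ny * nx * p * p
    n_blobs = rng.poisson(spec.count_density * area)
    mask = np.zeros((ny, nx), dtype=bool)
    if n_blobs == 0 or spec.intensity_scale == 0:
        data = image.data.copy()
        if n_blobs and spec.intensity_scale == 0:
            # zero-amplitude blobs still occupy their true-mask footprint
            centers = rng.uniform([0, 0], [nx * p, ny * p], size=(n_blobs, 2))
            _paint_mask(mask, centers, spec.radius_um, p)
        return ConfocalImage(data, p, dict(image.meta)), mask

    centers = rng.uniform([0, 0], [nx * p, ny * p], size=(n_blobs, 2))
    amplitude = spec.intensity_scale * float(np.median(image.data))
    sigma = spec.radius_um / 2.0
    added = np.zeros((ny, nx))
    xc = (np.arange(nx) + 0.5) * p
    yc = (np.arange(ny) + 0.5) * p
    r_px = max(int(np.ceil(4 * sigma / p)), 1)
    for x, y in centers:
        j0, i0 = int(x / p), int(y / p)
        jlo, jhi = max(j0 - r_px, 0), min(j0 + r_px + 1, nx)
        ilo, ihi = max(i0 - r_px, 0), min(i0 + r_px + 1, ny)
        if jlo >= jhi or ilo >= ihi:
            continue
        dx2 = (xc[jlo:jhi] - x) ** 2
        dy2 = (yc[ilo:ihi] - y) ** 2
        added[ilo:ihi, jlo:jhi] += amplitude * np.exp(
            -(dy2[:, None] + dx2[None, :]) / (2 * sigma**2)
        )
    _paint_mask(mask, centers, spec.radius_um, p)
    data = np.clip(np.rint(image.data.astype(float) + added), 0, 65535).astype(np.uint16)
    return ConfocalImage(data, p, dict(image.meta)), mask


def _paint_mask(mask: np.ndarray, centers_um: np.ndarray, radius_um: float, p: float) -> None:
    ny, nx = mask.shape
    r_px = max(int(np.ceil(radius_um / p)), 1)
    xc = (np.arange(nx) + 0.5) * p
    yc = (np.arange(ny) + 0.5) * p
    for x, y in centers_um:
        j0, i0 = int(x / p), int(y / p)
        jlo, jhi = max(j0 - r_px - 1, 0), min(j0 + r_px + 2, nx)
        ilo, ihi = max(i0 - r_px - 1, 0), min(i0 + r_px + 2, ny)
        if jlo >= jhi or ilo >= ihi:
            continue
        dx2 = (xc[jlo:jhi] - x) ** 2
        dy2 = (yc[ilo:ihi] - y) ** 2
        mask[ilo:ihi, jlo:jhi] |= (dy2[:, None] + dx2[None, :]) <= radius_um**2


def simulate_calibration_series(
    densities: list[float],
    q0: float,
    psf: PSFModel,
    detector: DetectorModel,
    seeds: list[int],
    shape_px: tuple[int, int] = (300, 300),
    pixel_size_um: float = 0.06,
) -> list[tuple[ConfocalImage, GroundTruthManifest]]:
    """Pure-monomer calibration images spanning a density range.

    The synthetic counterpart of imaging dilution series of a monomeric
    fluorophore standard; densities below 15 protomers/µm² are flagged
    ``below_calibration_floor`` in the manifest.
    """
    if len(seeds) != len(densities):
        raise ValueError("need one seed per density")
    out = []
    for d, s in zip(densities, seeds):
        if d <= 0:
            raise ValueError("calibration densities must be positive")
        mixture = SpeciesMixture.pure(1, d, q0=q0)
        img, manifest = simulate_image(mixture, psf, detector, shape_px, pixel_size_um, s)
        if d < CALIBRATION_DENSITY_FLOOR:
            manifest.flags.append("below_calibration_floor")
        out.append((img, manifest))
    return out


def simulate_patch_series(
    protomer_fractions: dict[int, float],
    n_patches: int,
    density_range: tuple[float, float],
    psf: PSFModel,
    detector: DetectorModel,
    seed: int,
    q0: float = 205.0,
    patch_shape_px: tuple[int, int] = (120, 120),
    pixel_size_um: float = 0.06,
) -> tuple[list[tuple[ConfocalImage, GroundTruthManifest]], dict[int, float]]:
    """Simulate a set of single-species membrane patches realising a target
    oligomer composition.

    Real membranes are compositionally patchy: an image segment is typically
    dominated by one oligomeric state, and the spectrogram decomposition is
    identifiable precisely because of that heterogeneity. This generator
    emulates it at the patch (image) scale: each patch carries one species at
    a protomer density drawn from an evenly spaced grid over
    ``density_range``, and the number of patches per species is proportional
    to its target protomer fraction. Species labels are interleaved across
    the density grid so every species samples the same densities.

    Returns the patches and the exact realised protomer fractions
    (patch-count based; by construction within 1/n_patches of the target).
    """
    if n_patches < 1:
        raise ValueError("need at least one patch")
    sizes = sorted(m for m, f in protomer_fractions.items() if f > 0)
    fracs = np.array([protomer_fractions[m] for m in sizes], dtype=float)
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0, atol=1e-9):
        raise ValueError("protomer fractions must be non-negative and sum to 1")
    # largest-remainder apportionment of patches to species
    raw = fracs * n_patches
    counts = np.floor(raw).astype(int)
    remainder = n_patches - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    if np.any((fracs > 0) & (counts == 0)):
        raise ValueError("too few patches to represent every species; increase n_patches")

    densities = np.linspace(density_range[0], density_range[1], n_patches)
    block = np.concatenate([np.full(c, m) for m, c in zip(sizes, counts)])
    # spread the species blocks over the density grid with a low-discrepancy
    # (golden-ratio) ordering so every species samples similar densities
    positions = np.argsort((np.arange(1, n_patches + 1) * 0.6180339887498949) % 1.0, kind="stable")
    labels = np.empty(n_patches, dtype=int)
    labels[positions] = block

    ss = np.random.SeedSequence(seed)
    patch_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_patches)]
    patches = []
    for m, d, s in zip(labels, densities, patch_seeds):
        mixture = SpeciesMixture.pure(int(m), float(d), q0=q0)
        patches.append(
            simulate_image(mixture, psf, detector, patch_shape_px, pixel_size_um, s)
        )
    # exact protomer weighting: patches share area, so weight by density
    realised = {
        int(m): float(densities[labels == m].sum() / densities.sum()) for m in sizes
    }
    return patches, realised
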