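"""Fluorescence intensity fluctuation (FIF) spectrometry.

Three stages, mirroring how the analysis is run on real data:

1. RoIs drawn on a confocal image are tiled into square 400-pixel segments.
2. Each segment's pixel-intensity histogram is fitted with a single
   Gaussian; the fitted mean and SD give an effective molecular brightness
   ε_eff (noise-corrected variance over γ-corrected mean, in a.u. per
   protomer) and a protomer surface concentration. ε_eff scales with
   oligomer size — a pure n-mer field gives ε_eff → n·q0 — while the
   concentration estimate is composition-invariant.
3. The frequency distribution of ε_eff across segments within each
   protomer-concentration bin (the brightness spectrogram) is decomposed
   into a sum of Gaussians whose centres are pinned at integer multiples of
   the monomeric brightness, yielding mole fractions of monomers, dimers
   and higher oligomers per concentration bin.

A despotting step can mask high-intensity punctae (endocytic vesicles)
before segmentation so they do not masquerade as bright oligomers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import binary_dilation

from .models import (
    ConfocalImage,
    DetectorModel,
    DEFAULT_GAMMA,
    DEFAULT_Q0,
    PSFModel,
)
from .psf_correlation import rect_mean_correlation
from .spida import psf_area, roi_mask

__all__ = [
    "Segment",
    "BrightnessSpectrogram",
    "OligomerFractions",
    "SegmentExcluded",
    "SEGMENT_AREA_PX",
    "DEFAULT_BIN_EDGES",
    "DENSITY_FLOOR",
    "segment_rois",
    "fit_segment_histogram",
    "effective_brightness",
    "segment_concentration",
    "analyze_segments",
    "despot",
    "build_spectrogram",
    "fit_oligomer_fractions",
    "pool_fractions",
    "compare_conditions",
]

SEGMENT_AREA_PX = 400  # 20 x 20 pixel squares
DENSITY_FLOOR = 15.0  # protomers/µm²; segments below are excluded
DEFAULT_BIN_EDGES = (15.0, 25.0, 35.0, 45.0, 55.0, 65.0)
MIN_SEGMENTS_PER_BIN = 20


class SegmentExcluded(Exception):
    """Raised when a segment carries no usable molecular signal."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class Segment:
    """One square tile of an RoI, carrying raw pixel values."""

    parent_roi: str
    row0: int
    col0: int
    pixels: np.ndarray  # (side, side) raw intensities

    @property
    def area_px(self) -> int:
        return int(self.pixels.size)


def segment_rois(
    image: ConfocalImage,
    rois: list,
    segment_px: int = 20,
    exclude_mask: np.ndarray | None = None,
) -> list[Segment]:
    """Tile each RoI polygon with non-overlapping ``segment_px``-square
    segments fully inside the polygon.

    The tiling is anchored at the top-left corner of the RoI bounding box;
    partial edge tiles are discarded. Segments overlapping ``exclude_mask``
    (e.g. a despot mask) are dropped. An RoI too small to hold a single full
    square yields no segments and a warning.
    """
    data = np.asarray(image.data)
    segments: list[Segment] = []
    for i, r in enumerate(rois):
        if isinstance(r, tuple) and len(r) == 2 and isinstance(r[0], str):
            name, verts = r
        else:
            name, verts = f"roi_{i}", r
        mask = roi_mask(image.shape, verts)
        if exclude_mask is not None:
            usable = mask & ~exclude_mask
        else:
            usable = mask
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            warnings.warn(f"RoI {name!r} rasterises to zero pixels")
            continue
        r0, c0 = rows.min(), cols.min()
        r1, c1 = rows.max() + 1, cols.max() + 1
        found = 0
        for rr in range(r0, r1 - segment_px + 1, segment_px):
            for cc in range(c0, c1 - segment_px + 1, segment_px):
                block = usable[rr : rr + segment_px, cc : cc + segment_px]
                if block.all():
                    segments.append(
                        Segment(name, rr, cc, data[rr : rr + segment_px, cc : cc + segment_px].copy())
                    )
                    found += 1
        if found == 0:
            warnings.warn(f"RoI {name!r} too small for a single {segment_px}x{segment_px} segment")
    return segments


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_segment_histogram(
    pixels: np.ndarray,
    histogram_bin_width: float | None = None,
) -> tuple[float, float, bool]:
    """Fit a single Gaussian to a segment's pixel-intensity histogram.

    Bin width defaults to Freedman–Diaconis with a floor of 1 a.u. The fit
    is initialised at the sample mean/SD; it is flagged not-ok when the
    optimiser fails or the fitted SD collapses below one bin width.

    Returns ``(mean, sd, fit_ok)``; on failure the sample moments are
    returned with ``fit_ok=False``.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    m0, s0 = float(x.mean()), float(x.std(ddof=1))
    if s0 == 0:
        return m0, 0.0, False
    if histogram_bin_width is None:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        histogram_bin_width = max(2.0 * iqr / x.size ** (1 / 3), 1.0)
    lo, hi = x.min(), x.max() + histogram_bin_width
    edges = np.arange(lo, hi + histogram_bin_width, histogram_bin_width)
    if len(edges) < 4:
        return m0, s0, False
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers,
            counts,
            p0=(counts.max(), m0, s0),
            bounds=(
                [0.0, m0 - 2 * s0, histogram_bin_width / 10.0],
                [2.0 * counts.max(), m0 + 2 * s0, 3.0 * s0],
            ),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return m0, s0, False
    _, mu, sigma = popt
    if sigma < histogram_bin_width:
        return float(mu), float(sigma), False
    return float(mu), float(sigma), True


def effective_brightness(
    mean_I: float,
    sd_I: float,
    detector: DetectorModel,
    gamma: float = DEFAULT_GAMMA,
    deflation: float = 1.0,
) -> float:
    """Effective brightness ε_eff (a.u./protomer) of a segment:

        ε_eff = (SD² − σ_det² − σ_bg²) / deflation / (γ·(⟨I⟩ − offset − I_bg))

    ``deflation`` is the finite-segment variance deflation ``1 − ρ̄`` from
    :mod:`fifspec.psf_correlation`; with it the estimator is unbiased under
    the Gaussian-PSF image model and a pure n-mer field gives ε_eff → n·q0.

    Raises :class:`SegmentExcluded` when the corrected mean or corrected
    variance is non-positive.
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    corrected_mean = mean_I - detector.offset - detector.background_mean
    corrected_var = (sd_I**2 - detector.noise_variance) / deflation
    if corrected_mean <= 0:
        raise SegmentExcluded("non_positive_corrected_mean")
    if corrected_var <= 0:
        raise SegmentExcluded("non_positive_corrected_variance")
    return corrected_var / (gamma * corrected_mean)


def segment_concentration(
    mean_I: float,
    detector: DetectorModel,
    q0_monomer: float = DEFAULT_Q0,
    gamma: float = DEFAULT_GAMMA,
    psf_area_um2: float | None = None,
    w_xy_um: float | None = None,
) -> float:
    """Protomer surface concentration (protomers/µm²) of a segment.

    C = (⟨I⟩ − offset − I_bg)·γ / (γ·q0·∬PSF) = corrected mean / (q0·∬PSF);
    independent of the oligomer composition because the mean intensity only
    counts protomers. Negative corrected means report 0 with a warning.
    """
    if psf_area_um2 is None:
        if w_xy_um is None:
            raise ValueError("provide psf_area_um2 or w_xy_um")
        psf_area_um2 = psf_area(w_xy_um)
    if q0_monomer <= 0 or psf_area_um2 <= 0:
        raise ValueError("q0 and PSF area must be positive")
    corrected = mean_I - detector.offset - detector.background_mean
    if corrected < 0:
        warnings.warn("corrected segment mean is negative; reporting concentration 0")
        return 0.0
    return corrected / (q0_monomer * psf_area_um2)


def analyze_segments(
    segments: list[Segment],
    detector: DetectorModel,
    psf: PSFModel,
    pixel_size_um: float,
    q0_monomer: float = DEFAULT_Q0,
    gamma: float = DEFAULT_GAMMA,
    replicate: str = "rep_0",
    correct_deflation: bool = True,
    estimator: str = "moments",
) -> pd.DataFrame:
    """Run stage-2 FIF on a list of segments.

    Returns a DataFrame with one row per segment: mean/SD, fit and
    exclusion flags with reason codes, ε_eff and protomer concentration.

    ``estimator`` selects the (mean, SD) fed into ε_eff and concentration:
    ``"moments"`` (default) uses the segment sample moments, which stay
    unbiased even for the strongly skewed pixel histograms of sparse
    oligomer fields where a single-Gaussian summary breaks down;
    ``"gaussian_fit"`` uses the fitted histogram parameters. The Gaussian
    fit is always performed and its success recorded as a quality flag —
    segments whose histogram cannot be fitted are excluded either way.
    """
    if estimator not in ("moments", "gaussian_fit"):
        raise ValueError("estimator must be 'moments' or 'gaussian_fit'")
    area = psf_area(psf.w_xy)
    rows = []
    deflation_cache: dict[tuple[int, int], float] = {}
    for seg in segments:
        shape = seg.pixels.shape
        if correct_deflation:
            if shape not in deflation_cache:
                deflation_cache[shape] = 1.0 - rect_mean_correlation(shape, psf.w_xy, pixel_size_um)
            deflation = deflation_cache[shape]
        else:
            deflation = 1.0
        fit_mean, fit_sd, ok = fit_segment_histogram(seg.pixels)
        x = seg.pixels.astype(float).ravel()
        if estimator == "moments":
            mean_i, sd_i = float(x.mean()), float(x.std(ddof=1))
        else:
            mean_i, sd_i = fit_mean, fit_sd
        row = {
            "roi": seg.parent_roi,
            "row0": seg.row0,
            "col0": seg.col0,
            "area_px": seg.area_px,
            "mean_I": mean_i,
            "sd_I": sd_i,
            "gaussian_fit_ok": ok,
            "eps_eff": np.nan,
            "concentration": np.nan,
            "excluded": False,
            "reason": "",
            "replicate": replicate,
        }
        if not ok:
            row["excluded"] = True
            row["reason"] = "gaussian_fit_failed"
        else:
            try:
                row["eps_eff"] = effective_brightness(mean_i, sd_i, detector, gamma, deflation)
                row["concentration"] = segment_concentration(
                    mean_i, detector, q0_monomer, gamma, area
                )
            except SegmentExcluded as exc:
                row["excluded"] = True
                row["reason"] = exc.reason
        rows.append(row)
    return pd.DataFrame(rows)


def despot(
    image: ConfocalImage,
    k: float = 5.0,
    dilate_px: int = 1,
    region_mask: np.ndarray | None = None,
) -> tuple[np.ma.MaskedArray, np.ndarray]:
    """Mask high-intensity punctae (vesicle-like spots).

    A pixel is flagged when it exceeds ``median + k·MAD`` of its region
    (the whole image, or ``region_mask`` if given), with the MAD scaled to
    be a consistent SD estimator; the flagged set is then dilated by
    ``dilate_px`` pixels. Flagged pixels are masked — excluded from
    segmentation — not inpainted.

    Returns ``(masked image, spot mask)``.
    """
    data = np.asarray(image.data, dtype=float)
    if region_mask is None:
        region = np.ones(data.shape, dtype=bool)
    else:
        region = np.asarray(region_mask, dtype=bool)
    vals = data[region]
    med = np.median(vals)
    mad = 1.4826 * np.median(np.abs(vals - med))
    if mad == 0:
        mad = max(vals.std(), 1.0)
    spot = (data > med + k * mad) & region
    if dilate_px > 0 and spot.any():
        size = 2 * dilate_px + 1
        spot = binary_dilation(spot, structure=np.ones((size, size), dtype=bool)) & region
    return np.ma.MaskedArray(image.data, mask=spot), spot


@dataclass
class ConcentrationBin:
    low: float
    high: float
    eps: np.ndarray
    replicates: np.ndarray

    @property
    def n(self) -> int:
        return int(self.eps.size)

    @property
    def low_n(self) -> bool:
        return self.n < MIN_SEGMENTS_PER_BIN


@dataclass
class BrightnessSpectrogram:
    """Per-concentration-bin frequency distributions of ε_eff."""

    bin_edges: tuple
    bins: list[ConcentrationBin]
    n_excluded_below_floor: int = 0
    n_excluded_above_range: int = 0

    @property
    def n_segments(self) -> int:
        return sum(b.n for b in self.bins)

    def histogram(self, bin_index: int, eps_bin_width: float) -> tuple[np.ndarray, np.ndarray]:
        b = self.bins[bin_index]
        if b.n == 0:
            return np.array([]), np.array([])
        lo = 0.0
        hi = np.ceil(b.eps.max() / eps_bin_width) * eps_bin_width
        edges = np.arange(lo, hi + eps_bin_width, eps_bin_width)
        counts, edges = np.histogram(b.eps, bins=edges)
        return counts, edges


def build_spectrogram(
    stats_df: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
) -> BrightnessSpectrogram:
    """Assign per-segment ε_eff values to protomer-concentration bins.

    Bins are half-open ``[low, high)`` (a value at an edge goes to the upper
    bin). Segments below the first edge (default 15 protomers/µm², where the
    monomer calibration is unreliable) or at/above the last edge are
    excluded; excluded or failed segments never contribute.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    ok = stats_df[~stats_df["excluded"] & np.isfinite(stats_df["eps_eff"])]
    conc = ok["concentration"].to_numpy()
    eps = ok["eps_eff"].to_numpy()
    reps = ok["replicate"].to_numpy()
    below = conc < edges[0]
    above = conc >= edges[-1]
    keep = ~(below | above)
    idx = np.searchsorted(edges, conc[keep], side="right") - 1
    bins = []
    for i in range(len(edges) - 1):
        sel = idx == i
        bins.append(
            ConcentrationBin(
                low=float(edges[i]),
                high=float(edges[i + 1]),
                eps=eps[keep][sel],
                replicates=reps[keep][sel],
            )
        )
    spect = BrightnessSpectrogram(
        bin_edges=tuple(edges),
        bins=bins,
        n_excluded_below_floor=int(below.sum()),
        n_excluded_above_range=int(above.sum()),
    )
    if spect.n_segments == 0:
        warnings.warn("no segments passed concentration filtering; spectrogram is empty")
    return spect


def _multi_gauss_fit(
    eps: np.ndarray,
    monomer_brightness: float,
    n_max: int,
    width_mode: str,
    seed: int = 0,
) -> tuple[np.ndarray, float, bool]:
    """Least-squares fit of Σ A_n·G(ε; n·ε1, σ_n) to an ε_eff histogram.

    Returns (areas_per_size, sigma1, ok); areas are Gaussian areas A_n·σ_n
    (∝ segment counts per species).
    """
    e1 = monomer_brightness
    hi = max((n_max + 1.0) * e1, float(np.percentile(eps, 99.5)))
    x = eps[(eps > 0) & (eps <= hi)]
    if x.size < 10:
        return np.zeros(n_max), np.nan, False
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    binw = max(2.0 * iqr / x.size ** (1 / 3), e1 / 16.0)
    edges = np.arange(0.0, hi + binw, binw)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ns = np.arange(1, n_max + 1)

    def sigmas(s1):
        return s1 * (np.sqrt(ns) if width_mode == "sqrt" else ns)

    def model(params):
        amps, s1 = params[:-1], params[-1]
        sg = sigmas(s1)
        return np.sum(
            amps[:, None] * np.exp(-((centers[None, :] - ns[:, None] * e1) ** 2) / (2 * sg[:, None] ** 2)),
            axis=0,
        )

    def resid(params):
        return model(params) - counts

    peak = counts.max()
    lower = np.concatenate([np.zeros(n_max), [binw / 2.0]])
    upper = np.concatenate([np.full(n_max, 4.0 * peak + 1.0), [1.5 * e1]])
    best = None
    for s1_frac in (0.2, 0.35, 0.55):
        a0 = np.interp(ns * e1, centers, counts, left=0.0, right=0.0)
        x0 = np.concatenate([np.maximum(a0, peak * 0.02), [s1_frac * e1]])
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lower, upper), max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost == np.inf:
        return np.zeros(n_max), np.nan, False
    amps, s1 = best.x[:-1], best.x[-1]
    areas = amps * sigmas(s1)
    if areas.sum() <= 0:
        return np.zeros(n_max), float(s1), False
    return areas, float(s1), True


def _areas_to_fractions(areas: np.ndarray, weighting: str) -> np.ndarray:
    ns = np.arange(1, len(areas) + 1)
    w = areas * ns if weighting == "protomer" else areas
    return w / w.sum()


@dataclass
class OligomerFractions:
    """Per-concentration-bin oligomer mole fractions.

    ``table`` has one row per bin with columns ``bin_low``, ``bin_high``,
    ``n_segments``, per-size fractions ``f_1`` … ``f_{n_max}``, the class
    fractions ``f_mono``/``f_di``/``f_oligo`` (sizes ≥ 3 pooled), matching
    ``sd_*`` columns (SD across replicates where available) and fit flags.
    """

    table: pd.DataFrame
    monomer_brightness: float
    n_max: int
    weighting: str
    width_mode: str
    replicate_tables: dict = field(default_factory=dict)


def fit_oligomer_fractions(
    spectrogram: BrightnessSpectrogram,
    monomer_brightness: float = DEFAULT_Q0,
    n_max: int = 4,
    weighting: str = "segment",
    width_mode: str = "linear",
    min_segments: int = MIN_SEGMENTS_PER_BIN,
) -> OligomerFractions:
    """Decompose each concentration bin's ε_eff distribution into oligomer
    fractions (stage-3 FIF).

    Gaussian peak centres are pinned at ``n·monomer_brightness`` for
    n = 1..n_max with non-negative amplitudes; peak widths share one free
    scale σ1 with σ_n = n·σ1 by default (the estimator noise of ε_eff is
    proportional to brightness; ``width_mode="sqrt"`` gives σ_n = √n·σ1).
    ``weighting`` converts fitted areas to mole fractions: ``segment``
    (default) treats each segment as representing an equal number of
    protomers — exact when bins are defined on protomer concentration —
    while ``protomer`` weights areas by oligomer size. Bins with fewer than
    ``min_segments`` segments, or where the optimiser fails, are flagged and
    carry no fractions.

    Cross-replicate SDs are computed by refitting each replicate's segments
    separately whenever at least two replicates have ``min_segments``
    segments in the bin.
    """
    if monomer_brightness <= 0:
        raise ValueError("monomer brightness must be positive")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if weighting not in ("segment", "protomer"):
        raise ValueError("weighting must be 'segment' or 'protomer'")
    if width_mode not in ("linear", "sqrt"):
        raise ValueError("width_mode must be 'linear' or 'sqrt'")

    size_cols = [f"f_{n}" for n in range(1, n_max + 1)]
    rows = []
    replicate_rows: dict[str, list] = {}
    for b in spectrogram.bins:
        row: dict = {
            "bin_low": b.low,
            "bin_high": b.high,
            "n_segments": b.n,
            "fit_ok": False,
            "flag": "",
            "sigma1": np.nan,
        }
        for c in size_cols + ["f_mono", "f_di", "f_oligo", "sd_mono", "sd_di", "sd_oligo"]:
            row[c] = np.nan
        if b.n < min_segments:
            row["flag"] = "low_n"
            rows.append(row)
            continue
        areas, s1, ok = _multi_gauss_fit(b.eps, monomer_brightness, n_max, width_mode)
        if not ok:
            row["flag"] = "fit_failed"
            rows.append(row)
            continue
        fr = _areas_to_fractions(areas, weighting)
        row.update({c: float(f) for c, f in zip(size_cols, fr)})
        row["f_mono"], row["f_di"], row["f_oligo"] = float(fr[0]), float(fr[1]), float(fr[2:].sum())
        row["fit_ok"] = True
        row["sigma1"] = s1

        # per-replicate refits for cross-replicate SD
        labels = np.unique(b.replicates)
        rep_fracs = []
        for lab in labels:
            eps_r = b.eps[b.replicates == lab]
            if eps_r.size < min_segments:
                continue
            a_r, _, ok_r = _multi_gauss_fit(eps_r, monomer_brightness, n_max, width_mode)
            if ok_r:
                fr_r = _areas_to_fractions(a_r, weighting)
                rep_fracs.append(fr_r)
                replicate_rows.setdefault(str(lab), []).append(
                    {"bin_low": b.low, "bin_high": b.high, "n_segments": int(eps_r.size),
                     "f_mono": fr_r[0], "f_di": fr_r[1], "f_oligo": float(fr_r[2:].sum())}
                )
        if len(rep_fracs) >= 2:
            rep = np.asarray(rep_fracs)
            row["sd_mono"] = float(rep[:, 0].std(ddof=1))
            row["sd_di"] = float(rep[:, 1].std(ddof=1))
            row["sd_oligo"] = float(rep[:, 2:].sum(axis=1).std(ddof=1))
        rows.append(row)
    table = pd.DataFrame(rows)
    rep_tables = {lab: pd.DataFrame(rws) for lab, rws in replicate_rows.items()}
    return OligomerFractions(
        table=table,
        monomer_brightness=monomer_brightness,
        n_max=n_max,
        weighting=weighting,
        width_mode=width_mode,
        replicate_tables=rep_tables,
    )


def pool_fractions(
    fractions: OligomerFractions,
    range_low: float = 25.0,
    range_high: float = 55.0,
) -> dict:
    """Segment-count-weighted pooling of per-bin fractions over a
    concentration range (default 25–55 protomers/µm², the window where the
    composition is stable and calibration is reliable).

    SDs are taken across replicate-wise pooled fractions when replicate
    refits exist, otherwise propagated from the per-bin SDs.
    """
    t = fractions.table
    sel = t[(t["bin_low"] >= range_low) & (t["bin_high"] <= range_high) & t["fit_ok"]]
    if sel.empty:
        raise ValueError(f"no fitted bins inside [{range_low}, {range_high})")
    w = sel["n_segments"].to_numpy(dtype=float)
    out = {"n_segments": int(w.sum()), "n_bins": len(sel)}
    for cls in ("mono", "di", "oligo"):
        out[f"f_{cls}"] = float(np.average(sel[f"f_{cls}"], weights=w))
    # replicate-level pooled values
    rep_labels: list[str] = []
    rep_pooled: list[list[float]] = []
    for lab, rt in fractions.replicate_tables.items():
        rsel = rt[(rt["bin_low"] >= range_low) & (rt["bin_high"] <= range_high)]
        if rsel.empty:
            continue
        rw = rsel["n_segments"].to_numpy(dtype=float)
        rep_labels.append(lab)
        rep_pooled.append([float(np.average(rsel[f"f_{c}"], weights=rw)) for c in ("mono", "di", "oligo")])
    if len(rep_pooled) >= 2:
        rp = np.asarray(rep_pooled)
        for j, cls in enumerate(("mono", "di", "oligo")):
            out[f"sd_{cls}"] = float(rp[:, j].std(ddof=1))
        out["n_replicates"] = len(rep_pooled)
        out["replicate_fractions"] = {
            lab: [float(v) for v in vec] for lab, vec in zip(rep_labels, rep_pooled)
        }
    else:
        for cls in ("mono", "di", "oligo"):
            sds = sel[f"sd_{cls}"].to_numpy(dtype=float)
            if np.all(np.isfinite(sds)):
                out[f"sd_{cls}"] = float(np.sqrt(np.sum((w * sds) ** 2)) / w.sum())
            else:
                out[f"sd_{cls}"] = float("nan")
    return out


_TIERS = ((1e-4, "****"), (1e-3, "***"), (0.05, "*"))


def _tier(p: float) -> str:
    for cut, label in _TIERS:
        if p < cut:
            return label
    return "ns"


def compare_conditions(per_condition_fractions: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA followed by Tukey's HSD across conditions, per species
    class.

    ``per_condition_fractions`` maps condition label → array of shape
    ``(n_replicates, 3)`` with columns monomer/dimer/oligomer fractions.
    Returns per class the ANOVA F and p plus pairwise Tukey p-values with
    significance tiers (*, ***, **** at 0.05, 0.001, 0.0001).
    """
    if len(per_condition_fractions) < 2:
        raise ValueError("need at least two conditions to compare")
    labels = list(per_condition_fractions)
    arrays = {}
    for lab in labels:
        a = np.asarray(per_condition_fractions[lab], dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError(f"condition {lab!r}: expected an (n_replicates, 3) fraction array")
        if a.shape[0] < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 replicates")
        arrays[lab] = a
    out: dict = {"conditions": labels, "classes": {}}
    for j, cls in enumerate(("monomer", "dimer", "oligomer")):
        groups = [arrays[lab][:, j] for lab in labels]
        f_stat, p = stats.f_oneway(*groups)
        res = stats.tukey_hsd(*groups)
        pairs = {}
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                pv = float(res.pvalue[a, b])
                pairs[f"{labels[a]} vs {labels[b]}"] = {"p": pv, "tier": _tier(pv)}
        out["classes"][cls] = {"anova_F": float(f_stat), "anova_p": float(p), "tukey": pairs}
    return out
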