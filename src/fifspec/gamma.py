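"""Confocal PSF shape factor γ and axial detection extent.

γ is the ratio ``∫PSF² / ∫PSF`` taken over the region of the sample that
contributes detected signal. It corrects molecular-brightness estimates for
the non-uniform illumination across the focal volume: a molecule at the
beam edge contributes less signal (and disproportionately less variance)
than one at the centre.

Canonical values (all reproduced here by quadrature):

* thin fluorophore layer in the focal plane, Gaussian beam: γ = 1/2,
  independent of the pinhole and of the waist;
* unbounded 3-D Gaussian focal volume: γ = 2^(−3/2) ≈ 0.354;
* uniform (flat-disk) PSF: γ = 1.

For a membrane imaged in axial cross-section the detected region is bounded
laterally by the back-projected pinhole and axially by the detection extent
ω_z; with a 1-Airy-unit pinhole the quadrature again gives γ ≈ 0.5, matching
the thin-layer value — which is why a single γ = 0.5 serves all membrane
orientations at PH = 1 AU.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .models import PSFModel, SampleGeometry

__all__ = [
    "gamma_factor",
    "axial_waist",
    "membrane_cross_section_gamma",
    "airy_unit_diameter",
]


def _axis_ratio(waist: float, half_limit: float | None, tol: float) -> tuple[float, float]:
    """(∫exp(-4u²/w²)du / ∫exp(-2u²/w²)du, error estimate) over [-a, a].

    ``half_limit=None`` integrates the full axis (ratio → 1/√2);
    a collapsed axis (a → 0) contributes a ratio of 1.
    """
    if half_limit is not None and half_limit <= 0:
        return 1.0, 0.0
    a = 6.0 * waist if half_limit is None else min(half_limit, 12.0 * waist)
    num, err_n = integrate.quad(lambda u: np.exp(-4.0 * u**2 / waist**2), -a, a, epsrel=tol, epsabs=0)
    den, err_d = integrate.quad(lambda u: np.exp(-2.0 * u**2 / waist**2), -a, a, epsrel=tol, epsabs=0)
    ratio = num / den
    err = ratio * (err_n / num + err_d / den)
    return ratio, err


def airy_unit_diameter(lambda_em_um: float = 0.555, numerical_aperture: float = 1.4) -> float:
    """Diameter of 1 Airy unit at the sample plane, 1.22·λ_em/NA (µm).

    λ_em defaults to the centre of a 505–605 nm detection band.
    """
    if lambda_em_um <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and NA must be positive")
    return 1.22 * lambda_em_um / numerical_aperture


def axial_waist(lambda_ex_um: float, n: float, NA: float, pinhole_um: float) -> float:
    """Axial extent ω_z of the confocal detection volume (µm).

    ω_z² = [0.88·λ_Ex / (n − √(n² − NA²))]² + [√2·n·PH / NA]²

    The first term is the diffraction-limited axial beam extent; the second
    is the geometric contribution of a pinhole of diameter PH (in sample
    units). ω_z is monotone increasing in both PH and λ_Ex.
    """
    if NA >= n:
        raise ValueError("NA must be smaller than the refractive index (imaginary root otherwise)")
    if min(lambda_ex_um, n, NA) <= 0 or pinhole_um < 0:
        raise ValueError("optical parameters must be positive (pinhole >= 0)")
    beam = 0.88 * lambda_ex_um / (n - np.sqrt(n**2 - NA**2))
    pin = np.sqrt(2.0) * n * pinhole_um / NA
    return float(np.hypot(beam, pin))


def gamma_factor(
    psf: PSFModel,
    geometry: SampleGeometry,
    quadrature_tolerance: float = 1e-6,
    return_error: bool = False,
):
    """Shape factor γ = ∫PSF²/∫PSF over the detected sample region.

    Supported combinations:

    * ``flat_disk`` PSF (any geometry): γ = 1 exactly (PSF² = PSF).
    * ``gaussian_2d`` + ``thin_layer_focal_plane``: 2-D quadrature over the
      focal plane; γ = 1/2, independent of w_xy.
    * ``gaussian_3d`` + ``solution_3d``: separable quadrature over the
      unbounded focal volume; γ = 2^(−3/2).
    * ``gaussian_3d`` + ``membrane_axial_cross_section``: see
      :func:`membrane_cross_section_gamma`.
    """
    tol = quadrature_tolerance
    if psf.form == "flat_disk":
        result, err = 1.0, 0.0
    elif geometry.kind == "thin_layer_focal_plane":
        rx, ex = _axis_ratio(psf.w_xy, None, tol)
        result, err = rx * rx, 2 * rx * ex
    elif geometry.kind == "solution_3d":
        if psf.form != "gaussian_3d" or psf.w_z is None:
            raise ValueError("solution_3d geometry requires a gaussian_3d PSF with an axial waist")
        rx, ex = _axis_ratio(psf.w_xy, None, tol)
        rz, ez = _axis_ratio(psf.w_z, None, tol)
        result = rx * rx * rz
        err = result * (2 * ex / rx + ez / rz)
    elif geometry.kind == "membrane_axial_cross_section":
        return membrane_cross_section_gamma(psf, geometry, tol, return_error=return_error)
    else:  # pragma: no cover - guarded by SampleGeometry validation
        raise ValueError(f"unsupported PSF/geometry combination: {psf.form}/{geometry.kind}")
    if err > max(tol, 1e-12) * max(result, 1e-12):
        raise RuntimeError(f"quadrature did not converge: error {err} for gamma {result}")
    return (result, err) if return_error else result


def membrane_cross_section_gamma(
    psf: PSFModel,
    geometry: SampleGeometry,
    quadrature_tolerance: float = 1e-6,
    return_error: bool = False,
):
    """γ for a membrane plane containing the optical axis.

    The detected region on the membrane plane is bounded laterally by the
    back-projected pinhole (half-extent PH/2 broadened by one lateral waist,
    since the geometric pinhole image is convolved with the detection PSF)
    and axially by the detection extent ω_z. The axial PSF waist is the
    diffraction-limited beam extent (the pinhole-free limit of ω_z); the
    pinhole enters only through the integration bounds.

    With a 1-AU pinhole both bounds comfortably cover their waists, each
    in-plane axis contributes a factor → 1/√2, and γ → 0.5; for very small
    pinholes the truncation pushes γ slightly above 0.5. γ ∈ (0.5, 1] …
    strictly (0, 1] … for every valid configuration.
    """
    if geometry.pinhole_um is None:
        raise ValueError("membrane cross-section gamma requires a pinhole diameter")
    tol = quadrature_tolerance
    n, NA, lam = geometry.refractive_index, geometry.numerical_aperture, geometry.lambda_ex_um
    w_z_beam = psf.w_z if psf.w_z is not None else axial_waist(lam, n, NA, 0.0)
    z_half = axial_waist(lam, n, NA, geometry.pinhole_um)
    x_half = geometry.pinhole_um / 2.0 + psf.w_xy
    rx, ex = _axis_ratio(psf.w_xy, x_half, tol)
    rz, ez = _axis_ratio(w_z_beam, z_half, tol)
    result = rx * rz
    err = result * (ex / rx + ez / rz) if result > 0 else 0.0
    return (result, err) if return_error else result
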