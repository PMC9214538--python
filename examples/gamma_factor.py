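"""PSF shape factor γ = ∫PSF²/∫PSF for the geometries a confocal
brightness experiment meets, plus the axial detection extent ω_z.

γ corrects molecular brightness for non-uniform illumination: 0.5 for a
thin fluorophore layer in the focal plane (and, with a 1-Airy-unit
pinhole, for any membrane orientation), 2^(−3/2) for a 3-D solution.
"""

import fifspec as fs
from fifspec.gamma import airy_unit_diameter

psf2d = fs.PSFModel(form="gaussian_2d")
psf3d = fs.PSFModel(form="gaussian_3d")

thin = fs.SampleGeometry(kind="thin_layer_focal_plane")
print(f"thin layer, Gaussian beam:        γ = {fs.gamma_factor(psf2d, thin):.4f}")

solution = fs.SampleGeometry(kind="solution_3d")
psf3d_z = fs.PSFModel(w_xy=0.2656, w_z=0.9, form="gaussian_3d")
print(f"unbounded 3-D solution:           γ = {fs.gamma_factor(psf3d_z, solution):.4f} "
      f"(closed form 2^-3/2 = {2**-1.5:.4f})")

au = airy_unit_diameter()  # 1.22·λ_em/NA = 0.484 µm at the sample
for au_frac in (0.5, 1.0, 2.0):
    geom = fs.SampleGeometry(kind="membrane_axial_cross_section", pinhole_um=au_frac * au)
    g = fs.membrane_cross_section_gamma(psf3d, geom)
    print(f"membrane cross-section, {au_frac:3.1f} AU:  γ = {g:.4f}")

wz = fs.axial_waist(0.488, 1.518, 1.4, au)
print(f"\naxial detection extent at 1 AU:   ω_z = {wz:.3f} µm")
print("\nAt a 1-Airy-unit pinhole the membrane-plane γ matches the thin-layer")
print("value, which is why a single γ = 0.5 serves all membrane orientations.")
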