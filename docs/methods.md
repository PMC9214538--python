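# Methods

`fifspec` quantifies the oligomeric state of fluorophore-tagged membrane
proteins from single confocal images by fluorescence fluctuation analysis:
SpIDA-style quantal-brightness calibration at the region-of-interest (RoI)
level, and FIF (fluorescence intensity fluctuation) spectrometry at the
segment level, backed by a forward simulator with exact moment oracles and
by numerical γ-factor theory. This note records the model, the estimators,
the numerical choices, and what the synthetic data do and do not establish.

## Image model and moment oracles

A membrane patch carries oligomeric species of size *m* (protomers) at
oligomer surface densities *C_m* (µm⁻²), scattered as independent 2-D
Poisson processes with uniform positions. The confocal PSF is a Gaussian
beam, lateral profile exp(−2r²/w_xy²) with unit peak; the default waist
w_xy = 0.2656 µm is the bead-measured reference value, sampled at 60-nm
pixels. A size-*m* molecule contributes m·q0·exp(−2r²/w_xy²) counts at a
pixel whose centre lies a distance *r* away, with q0 = 205 a.u. per
protomer at beam centre. Pixels additionally receive a constant detector
offset, Gaussian read noise, and a Gaussian autofluorescence background,
then are clipped to [0, 65535] and quantised to 16-bit integers.

Campbell's theorem gives the exact pre-quantisation pixel moments:

```
mean = offset + I_bg + Σ_m C_m · m·q0 · A_PSF          A_PSF = (1/2)·π·w_xy²
var  = σ_det² + σ_bg² + Σ_m C_m · (m·q0)² · γ·A_PSF    γ = ∫PSF²/∫PSF = 1/2
```

`closed_form_moments` implements these and is the oracle every brightness
estimator is validated against. Two deliberate simplifications, both
documented here because they bound the oracle's accuracy:

* **Point-sampled PSF.** Pixel values sample the field at pixel centres
  rather than integrating over the pixel area; with 60-nm pixels versus a
  266-nm waist the error is below 1%.
* **Quantisation ignored.** Rounding adds at most 1/12 a.u.² of variance,
  negligible against typical signal variances of 10⁴–10⁵ a.u.².

Detector defaults — offset 100, read-noise SD 20, background 100 ± 20
a.u. — represent a quiet photomultiplier with moderate cellular
autofluorescence; none is critical, since every estimator subtracts them
explicitly. A signal-proportional variance term (`shot_noise_gain`) models
gain-scaled photon shot noise; it is off by default because the reference
imaging protocol quantifies detector noise empirically rather than
prescribing a gain model, and all noise terms that are enabled appear in
the oracle symmetrically.

Simulated fields extend 4 waists beyond the image border so edge pixels
receive the PSF tails they would in a larger sample.

## Finite-region variance deflation

The molecular shot-noise field has spatial covariance ∝ exp(−d²/w_xy²)
(the PSF autocorrelation), so pixels within ~w_xy of each other are
strongly correlated. The sample variance over a small region therefore
*underestimates* the true pixel variance by the factor 1 − ρ̄, where ρ̄ is
the mean pairwise correlation over all pixel pairs of the region. This is
not a small effect at FIF's scales: for a 20×20-pixel segment at 60-nm
pixels, 1 − ρ̄ ≈ 0.88, i.e. a −12% bias on any variance-based brightness
estimate; for a 100×100-pixel RoI it is ≈ −2%.

`fifspec.psf_correlation` computes ρ̄ in closed form for rectangles
(separable sums) and by FFT autocorrelation for arbitrary masks, and the
brightness estimators divide the noise-corrected variance by 1 − ρ̄. The
correction is analytic — derived from the same image model as the moment
oracle, with no fitted constants — and makes ε_eff and QB unbiased for the
simulator's ground truth. Omitting it (deflation = 1) reproduces the naive
estimator for comparison.

## Quantal brightness, MEUs and the monomer boundary

Per RoI, QB = (Var[I] − σ_det² − σ_bg²) / (⟨I⟩ − offset − I_bg), which for
a monomeric field equals γ·q0. RoIs whose corrected mean is non-positive
carry no signal and are excluded with a reason code; an all-excluded
calibration is an error. QB values are expressed in monomeric equivalent
units (MEU = QB / reference QB) and the monomer/higher-order boundary is
1 + 1.96·(SD/mean), rounded to three decimals — 95% coverage of a Gaussian
monomer population (the reference calibration, 113.5 ± 13.2, gives 1.228;
classification at the boundary is inclusive, i.e. monomeric). Normality of
an MEU sample is assessed with both the D'Agostino–Pearson and
Shapiro–Wilk tests plus a 0.2-MEU-bin histogram.

Two estimator properties matter when designing a calibration:

* The QB ratio cancels the local realised density to first order, so QB is
  density-invariant (verified from 20 to 100 protomers/µm²).
* The variance estimator is chi-square-like with an effective degree count
  proportional to RoI area, giving the per-RoI QB a right skew ∝
  1/√(RoI area): skew ≈ 0.34 for 60×60-pixel RoIs but ≈ 0.15 for
  100×100-pixel RoIs. Calibrations drawn on uniform solutions should use
  large RoIs (the default study condition uses 100×100 px = 6×6 µm);
  with small RoIs even a perfectly monomeric field can fail strict
  normality testing because of estimator skew, not biology.

Concentration follows from the corrected mean: N = [I]/QB particles per
beam area, and C = N·γ / A_PSF molecules/µm², with A_PSF = (1/2)π w_xy²
(0.111 µm² at the reference waist).

## FIF spectrometry

**Stage 1 — segmentation.** RoI polygons (0-based pixel-corner
coordinates; a pixel belongs to the RoI iff its centre is inside) are
tiled with non-overlapping 20×20-pixel squares anchored at the RoI
bounding-box top-left corner; partial tiles are discarded and segments
touching a despot mask are dropped.

**Stage 2 — per-segment brightness and concentration.** Each segment's
pixel histogram is fitted with a single Gaussian (Freedman–Diaconis bin
width, floor 1 a.u., initialised at the sample moments; the fit is flagged
failed when the optimiser fails or the fitted SD collapses below one bin
width). The effective brightness is

```
ε_eff = (SD² − σ_det² − σ_bg²) / (1 − ρ̄) / (γ·(⟨I⟩ − offset − I_bg))
```

and the protomer concentration is (⟨I⟩ − offset − I_bg)/(q0·A_PSF),
independent of composition. By default the moments entering these formulas
are the segment *sample* moments, with the Gaussian fit serving as a
quality gate (`estimator="gaussian_fit"` switches to the fitted
parameters). The reason is statistical: at ~1 oligomer per beam area —
routine for tetramers at 40 protomers/µm² — segment histograms are
strongly skewed, and a Gaussian summary of them biases the mean low by
tens of percent and occasionally inflates the fitted SD catastrophically,
while the sample moments remain unbiased for the model's first two
moments, which is all ε_eff and C consume. Segments with non-positive
corrected mean or variance are excluded with machine-readable reasons.

**Stage 3 — spectrogram decomposition.** Per-segment ε_eff values are
binned by protomer concentration (default edges 15, 25, …, 65 µm⁻²,
half-open upward; below 15 µm⁻² the monomer calibration is unreliable and
segments are excluded). Each bin's ε_eff histogram is fitted by least
squares with Σₙ Aₙ·G(ε; n·q0, σₙ), n = 1…4: centres pinned at integer
multiples of the monomeric brightness, amplitudes bounded non-negative,
and one free width scale σ₁ with σₙ = n·σ₁. The linear width scaling is a
measured property of the estimator — ε_eff's relative SD is ~35%
regardless of oligomer size, because the variance estimator's noise is
proportional to the variance itself — and a √n alternative remains
available. Fitting uses trust-region least squares with three σ₁ starts
(0.2, 0.35, 0.55 × q0), keeping the lowest-cost solution. Bins with fewer
than 20 segments, or failed fits, are flagged and carry no fractions.

Fitted areas convert to mole fractions by **segment-count weighting**
(fₙ = areaₙ/Σarea): because bins are defined on *protomer* concentration,
every segment in a bin represents the same number of protomers, so segment
counts are already protomer-weighted. An oligomer-number weighting
(n·areaₙ, appropriate if segments shared oligomer rather than protomer
density) is available via `weighting="protomer"`. Sizes ≥ 3 are pooled
into the oligomer class. Fractions are pooled over 25–55 protomers/µm²
(segment-count-weighted), with SDs taken across replicate-wise refits, and
conditions are compared per class by one-way ANOVA followed by Tukey's
HSD, reported with 0.05 / 0.001 / 0.0001 significance tiers.

**Despotting.** High-intensity punctae (endocytic vesicles) are masked
before segmentation: pixels above median + 5·MAD of their region (MAD
scaled 1.4826 for normal consistency), dilated by one pixel. Masked pixels
are excluded, never inpainted. On simulated contamination (Gaussian blobs,
10× the image median, radius 0.3 µm, 0.05–0.08 µm⁻²) the mask recovers
essentially all puncta pixels at ~1% false positives and leaves the
recovered monomer fraction within a few points of the clean value.

## What the synthetic data emulate — and what they do not

The generator realises uniform planar Poisson fields per species, which is
the regime in which the moment oracles are exact. One structural point
deserves emphasis: if all species are co-mixed uniformly at sub-segment
scale, every segment sees the same composition and the brightness
spectrogram collapses to a single peak at the intensity-weighted mean
brightness — *no* decomposition method could recover the fractions from
it. The information the multi-Gaussian fit exploits is compositional
heterogeneity between segments, which real membranes exhibit (distinct
spectrogram peaks at multiples of the monomer brightness). The
fraction-recovery study conditions therefore simulate *patchworks*:
single-species patches whose patch counts are proportional to the target
protomer fractions, at densities interleaved over 28–52 protomers/µm² by a
golden-ratio ordering so every species samples the same density range.
Recovery of {pure monomer; 50/50 monomer–dimer; 15/40/45 and 44/36/20
monomer/dimer/tetramer} within ±0.10 per class (≥8/10 seeds, ≥300
segments) demonstrates the estimator chain end to end under that
patchiness assumption; it does not establish performance when a single
segment straddles a compositional boundary, under molecular diffusion or
photobleaching, in 3-D geometries, or for the intermediate mixing scales
of real neurons.

## γ-factor theory

γ = ∭PSF²/∭PSF over the detected sample region, computed by adaptive
quadrature (separable axis integrals, domains truncated at 6 waists where
unbounded — the truncated Gaussian tail is < e⁻³² ≈ 1e-14 relative — with
relative tolerance 1e-6 and a propagated error estimate). Closed-form
anchors: 0.5 for a thin layer in the focal plane under a 2-D Gaussian
(waist-invariant), 2^(−3/2) for an unbounded 3-D Gaussian volume, exactly
1 for a flat-disk PSF.

For a membrane parallel to the optical axis the detected region on the
membrane plane is bounded laterally by the back-projected pinhole and
axially by the detection extent

```
ω_z = √{ [0.88·λ_Ex/(n − √(n² − NA²))]² + [√2·n·PH/NA]² }
```

(the pinhole-free first term is also the axial PSF extent). The lateral
half-bound is taken as PH/2 + w_xy, since the geometric pinhole image is
convolved with the detection PSF. With a 1-Airy-unit pinhole
(1 AU = 1.22·λ_em/NA, λ_em defaulting to 0.555 µm, the centre of a
505–605-nm detection band) both bounds comfortably cover their waists,
each in-plane axis contributes a factor → 1/√2, and the quadrature returns
γ = 0.500 — the reason a single γ = 0.5 serves every membrane orientation
at the standard pinhole setting. For very small pinholes the truncation
raises γ slightly (0.52 at 0.25 AU); γ lies in (0, 1] for every valid
configuration by the Cauchy–Schwarz bound on the ratio.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.Generator` seeded per run, with
per-stage streams spawned via `SeedSequence`; identical config + inputs +
seed give byte-identical CSV outputs. The validation suite uses problem
sizes chosen to put Monte-Carlo error well inside each tolerance while
keeping a laptop-scale footprint: ≥10⁶ pixels per mixture for the moment
oracles (16 replicate 250² images, with variance computed about the
analytic mean because pixel correlation biases within-image estimates),
~580–900 segments per fraction-recovery run (16–25 patches of 120²
pixels), and 100-seed replication for the normality and significance-power
checks.

## Known limitations

* 2-D only: no z-stacks, no axial sectioning of thick samples, no
  neuronal morphology; RoIs are supplied, not proposed.
* No diffusion, blinking or photobleaching; molecules are static during
  the (implicit) exposure.
* The multi-Gaussian decomposition assumes segments are dominated by one
  species; thoroughly co-mixed populations are fundamentally unidentifiable
  from a single-image spectrogram (see above).
* Brightness drift of the reference fluorophore (e.g. an effective γ
  change when membrane folding is lost after vesiculation) is not
  corrected; spectrograms shifted below the monomer line are reported
  as-is.
* n_max defaults to 4; larger aggregates alias into the oligomer class.
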