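"""Full FIF spectrometry on a simulated membrane with a known oligomer
composition: segmentation, per-segment brightness, brightness spectrogram
and constrained multi-Gaussian decomposition into species fractions.

The ground truth is 15% monomer / 40% dimer / 45% tetramer (protomer mole
fractions) distributed over single-species membrane patches at 28–52
protomers/µm², the compositional patchiness that makes the decomposition
identifiable.
"""

import numpy as np
import pandas as pd

import fifspec as fs

psf = fs.PSFModel()
detector = fs.DetectorModel()

patches, truth = fs.simulate_patch_series(
    {1: 0.15, 2: 0.40, 4: 0.45}, 20, (28.0, 52.0), psf, detector, seed=21,
    patch_shape_px=(120, 120),
)

frames = []
roi = [("patch", np.array([(0.0, 0.0), (120.0, 0.0), (120.0, 120.0), (0.0, 120.0)]))]
for image, _ in patches:
    segments = fs.segment_rois(image, roi)
    frames.append(fs.analyze_segments(segments, detector, psf, 0.06))
stats = pd.concat(frames, ignore_index=True)

spect = fs.build_spectrogram(stats)
fractions = fs.fit_oligomer_fractions(spect)
pooled = fs.pool_fractions(fractions)

print(f"segments analysed: {spect.n_segments} "
      f"(excluded below 15/µm²: {spect.n_excluded_below_floor})")
ok = stats[~stats["excluded"]]
print(f"ε_eff range: {ok['eps_eff'].quantile(0.05):.0f}–{ok['eps_eff'].quantile(0.95):.0f} a.u. "
      "(monomer = 205, dimer = 410, tetramer = 820)")
print("\nper-bin fractions:")
cols = ["bin_low", "bin_high", "n_segments", "f_mono", "f_di", "f_oligo"]
print(fractions.table.loc[fractions.table["fit_ok"], cols].to_string(index=False, float_format="%.3f"))
print("\npooled over 25–55 protomers/µm²:")
for cls, key in (("monomer", 1), ("dimer", 2), ("oligomer", 4)):
    t = truth.get(key, 0.0) if key != 4 else sum(v for k, v in truth.items() if k >= 3)
    print(f"  {cls:8s}: recovered {pooled['f_' + ('mono' if key == 1 else 'di' if key == 2 else 'oligo')]:.3f}  "
          f"(simulated truth {t:.3f})")
print("\nRecovered mole fractions track the truth within the method's working")
print("accuracy (±0.1 per class at this segment count); the spectrogram peaks")
print("at multiples of 205 a.u. identify the species.")
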