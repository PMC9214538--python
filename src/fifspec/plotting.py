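"""Spectrogram and fraction plots."""

from __future__ import annotations

import numpy as np

from .fif import BrightnessSpectrogram, OligomerFractions


def plot_spectrogram(
    spect: BrightnessSpectrogram,
    monomer_brightness: float = 205.0,
    eps_bin_width: float = 25.0,
    ax=None,
):
    """Wire-histogram brightness spectrogram: one ε_eff frequency curve per
    concentration bin, with the expected pure-monomer brightness marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, b in enumerate(spect.bins):
        if b.n == 0:
            continue
        counts, edges = spect.histogram(i, eps_bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(centers, counts, drawstyle="steps-mid", label=f"{b.low:.0f}–{b.high:.0f}/µm² (n={b.n})")
    ax.axvline(monomer_brightness, ls=":", color="k", label=f"monomer ({monomer_brightness:.0f})")
    ax.set_xlabel(r"$\varepsilon_\mathrm{eff}$ (a.u./protomer)")
    ax.set_ylabel("segments")
    ax.legend(fontsize=7)
    return ax


def plot_fractions(fractions: OligomerFractions, ax=None):
    """Stacked oligomer fractions per concentration bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = fractions.table[fractions.table["fit_ok"]]
    centers = 0.5 * (t["bin_low"] + t["bin_high"])
    bottom = np.zeros(len(t))
    for col, lab in (("f_mono", "monomer"), ("f_di", "dimer"), ("f_oligo", "oligomer")):
        vals = t[col].to_numpy()
        ax.bar(centers, vals, width=8.0, bottom=bottom, label=lab)
        bottom += vals
    ax.set_xlabel("protomer concentration (protomers/µm²)")
    ax.set_ylabel("mole fraction")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
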