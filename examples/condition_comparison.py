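"""Two-condition experiment through the full pipeline: a basal membrane
population rich in dimers/oligomers versus a ligand-treated one shifted
toward monomers, each with three simulated replicates, compared by one-way
ANOVA with Tukey's HSD per species class.
"""

from fifspec.pipeline import RunConfig, run_pipeline

config = RunConfig(
    seed=3,
    output_dir="fifspec_demo_run",
    conditions=[
        {"label": "basal",
         "simulate": {"fractions": {1: 0.15, 2: 0.40, 4: 0.45},
                      "n_patches": 21, "replicates": 3}},
        {"label": "ligand",
         "simulate": {"fractions": {1: 0.44, 2: 0.36, 4: 0.20},
                      "n_patches": 21, "replicates": 3}},
    ],
)

summary = run_pipeline(config)

for label, pooled in summary["conditions"].items():
    print(f"{label:7s}: monomer {pooled['f_mono']:.3f} ± {pooled.get('sd_mono', float('nan')):.3f}, "
          f"dimer {pooled['f_di']:.3f}, oligomer {pooled['f_oligo']:.3f} "
          f"({pooled['n_segments']} segments)")

print()
for cls, res in summary["comparison"]["classes"].items():
    pair = next(iter(res["tukey"].values()))
    print(f"{cls:8s}: ANOVA p = {res['anova_p']:.4g}, Tukey p = {pair['p']:.4g} ({pair['tier']})")
print("\nA significant monomer increase under ligand mirrors how receptor")
print("pharmacology shifts the oligomer equilibrium; artifacts are in",
      config.output_dir + "/")
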