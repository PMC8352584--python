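"""Classify genes across a strain panel.

Recovers the planted commonly-deleterious set (genes whose overexpression
is deleterious in >=66% of strains), derives strain-specific lists, and
prints the strain-count histogram.
"""

import ampfit

cfg = ampfit.SimulationConfig(seed=7, n_genes=2000,
                              strains=ampfit.default_strains(8))
matrix, truth, _ = ampfit.simulate_experiment(cfg)
table = ampfit.score_experiment(matrix)
result = ampfit.classify_experiment(table)

threshold = ampfit.strain_count_threshold(len(matrix.strains), 0.66)
recovered = result["commonly_deleterious"]
planted = truth.common_genes
print(f"commonly deleterious = deleterious in >= {threshold} of "
      f"{len(matrix.strains)} strains")
print(f"planted {len(planted)}, recovered {len(recovered)}, "
      f"overlap {len(recovered & planted)}")
print("strain-count histogram (k strains -> genes deleterious in exactly k):")
for k, n in result["histogram"].items():
    print(f"  {k:2d} strains: {n} genes")
specific = result["strain_specific"]
print("strain-specific genes (significant in <=2 other strains):",
      {s: len(g) for s, g in specific.items()})
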