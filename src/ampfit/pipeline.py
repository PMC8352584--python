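"""End-to-end driver: counts -> normalized scores -> NB tests -> calls.

`score_experiment` stitches the stages together the way the screen is
analysed in practice: library-size normalization, end-point dropout
imputation with renormalization, per-replicate log2 fitness scores, a
per-strain negative-binomial generation test with BH FDR, and
direction calls.  The result is a tidy fitness table with one row per
gene x strain, suitable for `ampfit.classify` and `ampfit.enrich`.
"""

from __future__ import annotations

import pandas as pd

from . import classify, diffabund, fitness
from .io import BarcodeCountMatrix


def score_experiment(
    m: BarcodeCountMatrix,
    min_norm_count: float = 20.0,
    impute: bool = True,
    prior_n: float = 10.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the full per-gene analysis and return the fitness table.

    Columns: gene_id, strain, mean_score, n_replicates_measured, imputed,
    log2fc, se, p_value, fdr, direction, plus one ``score_rep<r>`` column
    per replicate.  FDR is computed per strain.
    """
    if impute:
        m2, norm, imputed = fitness.renormalized_after_imputation(m, min_norm_count)
    else:
        m2, imputed = m, set()
        norm = fitness.normalize_library_size(m)
    table = fitness.fitness_scores(norm, m2, imputed)

    tests = []
    for strain in m2.strains:
        res = diffabund.fit_strain(m2, strain, prior_n=prior_n)
        res = res.reset_index().rename(columns={"index": "gene_id"})
        res["strain"] = strain
        tests.append(res[["gene_id", "strain", "log2fc", "se", "p_value", "fdr"]])
    table = table.merge(pd.concat(tests, ignore_index=True),
                        on=["gene_id", "strain"], how="left")
    return classify.annotate_directions(table, fdr_threshold)


def classify_experiment(
    table: pd.DataFrame,
    fdr_threshold: float = 0.05,
    common_fraction: float = 0.66,
    max_others: int = 2,
) -> dict:
    """Derive the standard gene-set taxonomy from a fitness table."""
    sets = classify.call_directions(table, fdr_threshold)
    return {
        "sets": sets,
        "commonly_deleterious": classify.commonly_deleterious(sets, common_fraction),
        "strain_specific": classify.strain_specific(sets, max_others),
        "histogram": classify.strain_count_histogram(sets),
    }
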