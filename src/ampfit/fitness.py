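"""Library-size normalization, end-point dropout imputation and per-gene
log2 relative fitness scores.

The screen measures, per strain, the change in relative barcode abundance
between generation 0 (thawed starting pool) and generation 10 of pooled
competitive growth.  Counts are normalized to reads per million within each
sample.  A barcode clearly present in every starting replicate (normalized
count >= ``min_norm_count``, default 20) but unobserved in an end-point
sample receives a single pseudocount there, so extreme depletion remains
testable instead of vanishing.  The replicate fitness score is
``log2(end-point RPM / starting RPM)``; negative scores mean the
overexpressed gene is deleterious.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .io import BarcodeCountMatrix, REP_SCORE_PREFIX

MILLION = 1_000_000.0


def normalize_library_size(m: BarcodeCountMatrix) -> pd.DataFrame:
    """Reads-per-million normalization: each column is divided by its total
    and rescaled to 1e6.  A zero column total is a hard error."""
    totals = m.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return m.counts / totals * MILLION


def impute_dropouts(
    m: BarcodeCountMatrix,
    norm: pd.DataFrame,
    min_norm_count: float = 20.0,
) -> tuple[BarcodeCountMatrix, set]:
    """Add a pseudocount of 1 to end-point dropouts of well-represented genes.

    Per strain, a gene qualifies when its normalized starting count is at
    least ``min_norm_count`` in ALL replicates of that strain; each end-point
    sample in which its raw count is missing (0, or NA in the input) then
    receives +1 raw read.  Returns a new matrix (input untouched) and the set
    of imputed ``(gene_id, strain)`` pairs.  Callers should renormalize the
    affected columns afterwards (see :func:`renormalized_after_imputation`).
    """
    out = m.copy()
    imputed: set = set()
    g0, g1 = m.generations
    for strain in m.strains:
        pairs = m.replicate_pairs(strain)
        start_cols = [s0 for _, s0, _ in pairs]
        eligible = (norm[start_cols] >= min_norm_count).all(axis=1)
        for _, _, s1 in pairs:
            absent = (m.counts[s1] == 0) | m.missing[s1]
            hit = eligible & absent
            if hit.any():
                out.counts.loc[hit, s1] += 1
                imputed.update((g, strain) for g in m.gene_ids[hit])
    return out, imputed


def renormalized_after_imputation(
    m: BarcodeCountMatrix, min_norm_count: float = 20.0
) -> tuple[BarcodeCountMatrix, pd.DataFrame, set]:
    """Convenience: normalize, impute, renormalize.  Returns the imputed raw
    matrix, its normalized matrix, and the imputed (gene, strain) set."""
    norm = normalize_library_size(m)
    m2, imputed = impute_dropouts(m, norm, min_norm_count)
    return m2, normalize_library_size(m2), imputed


def fitness_scores(
    norm: pd.DataFrame,
    m: BarcodeCountMatrix,
    imputed: set | frozenset = frozenset(),
) -> pd.DataFrame:
    """Per-(gene, strain) replicate and mean log2 fitness scores.

    A replicate score is ``log2(norm_end / norm_start)`` and is defined only
    when both normalized counts are positive; the mean is taken over defined
    replicate scores and ``n_replicates_measured`` counts them.  Returns a
    tidy table with one row per gene x strain and ``score_rep<r>`` columns.
    """
    frames = []
    for strain in m.strains:
        pairs = m.replicate_pairs(strain)
        rep_scores = {}
        for rep, s0, s1 in pairs:
            n0 = norm[s0].to_numpy(float)
            n1 = norm[s1].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.log2(n1 / n0)
            score[(n0 <= 0) | (n1 <= 0)] = np.nan
            rep_scores[f"{REP_SCORE_PREFIX}{rep}"] = score
        sub = pd.DataFrame(rep_scores, index=m.gene_ids)
        arr = sub.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mean = np.nanmean(arr, axis=1)
        sub.insert(0, "gene_id", m.gene_ids)
        sub.insert(1, "strain", strain)
        sub.insert(2, "mean_score", mean)
        sub.insert(3, "n_replicates_measured", np.isfinite(arr).sum(axis=1))
        sub.insert(4, "imputed", [(g, strain) in imputed for g in m.gene_ids])
        frames.append(sub.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def qc_replicate_correlation(
    table: pd.DataFrame, min_genes: int = 10
) -> dict[str, float]:
    """Mean pairwise Pearson correlation of per-replicate log2 scores.

    Per strain, correlations are computed over genes scored in both members
    of each replicate pair (at least ``min_genes`` genes required) and
    averaged over pairs.  Strains without a usable pair map to NaN with a
    warning.
    """
    out: dict[str, float] = {}
    for strain, sub in table.groupby("strain", sort=False):
        rep_cols = [
            c for c in sub.columns
            if c.startswith(REP_SCORE_PREFIX) and sub[c].notna().any()
        ]
        corrs = []
        for a, b in itertools.combinations(rep_cols, 2):
            ok = sub[a].notna() & sub[b].notna()
            if ok.sum() < min_genes:
                continue
            corrs.append(float(np.corrcoef(sub.loc[ok, a], sub.loc[ok, b])[0, 1]))
        if corrs:
            out[strain] = float(np.mean(corrs))
        else:
            warnings.warn(f"strain {strain!r}: <2 usable replicates for QC")
            out[strain] = float("nan")
    return out
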