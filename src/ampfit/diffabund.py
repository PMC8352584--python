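"""Negative-binomial test for barcode-abundance change between generations.

This is a self-contained two-group count test in the spirit of the standard
Bar-seq analysis: per-gene negative-binomial dispersions are estimated by
method of moments on within-generation residuals (with library-size
offsets), stabilised by empirical-Bayes shrinkage toward a trimmed common
value, and the generation effect is assessed with a Wald test on the log2
ratio of offset-corrected group rates.  Multiple testing is handled by
Benjamini-Hochberg step-up FDR.

Model: count ~ NB(mean mu, dispersion phi) with Var = mu + phi * mu^2;
phi = 0 degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BarcodeCountMatrix

LN2 = np.log(2.0)


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions with their shrinkage bookkeeping."""

    common: float
    tagwise: pd.Series
    raw: pd.Series
    shrinkage_weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.common) or self.common < 0:
            raise ValueError("common dispersion must be finite and >= 0")


def _group_columns(m: BarcodeCountMatrix) -> tuple[list, list]:
    g0, g1 = m.generations
    cols0 = list(m.samples.index[m.samples["generation"] == g0])
    cols1 = list(m.samples.index[m.samples["generation"] == g1])
    return cols0, cols1


def estimate_dispersions(
    m: BarcodeCountMatrix,
    prior_n: float = 10.0,
    trim: float = 0.05,
) -> DispersionEstimates:
    """Moment-based dispersion estimation with shrinkage.

    Counts are rescaled to the mean library size; within each generation
    group the raw per-gene dispersion is ``max(0, (v - mu) / mu^2)`` from the
    group mean ``mu`` and sample variance ``v``, pooled across groups with
    degree-of-freedom weights.  The common dispersion is a two-sided trimmed
    mean over genes, and tagwise values shrink the raw estimates toward it
    with weight ``w = prior_n / (prior_n + r)`` where ``r`` is the residual
    degrees of freedom.  Any group with a single replicate is an error.
    """
    cols0, cols1 = _group_columns(m)
    if len(cols0) < 2 or len(cols1) < 2:
        raise ValueError("need >= 2 replicates in each generation group")
    lib = m.counts.sum(axis=0).astype(float)
    scale = lib.mean() / lib
    adj = m.counts.to_numpy(float) * scale.to_numpy()[None, :]
    idx = {c: i for i, c in enumerate(m.counts.columns)}

    num = np.zeros(m.counts.shape[0])
    den = np.zeros(m.counts.shape[0])
    resid_df = 0
    for cols in (cols0, cols1):
        sel = adj[:, [idx[c] for c in cols]]
        n = sel.shape[1]
        mu = sel.mean(axis=1)
        v = sel.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - mu) / mu**2
        w = float(n - 1)
        ok = mu > 0
        num[ok] += w * phi_g[ok]
        den[ok] += w
        resid_df += n - 1

    raw = np.zeros(m.counts.shape[0])
    defined = den > 0
    raw[defined] = np.maximum(0.0, num[defined] / den[defined])
    if defined.any():
        common = float(stats.trim_mean(raw[defined], trim))
    else:
        common = 0.0
    w_shrink = prior_n / (prior_n + resid_df)
    tagwise = np.maximum(0.0, (1.0 - w_shrink) * raw + w_shrink * common)
    tagwise[~defined] = common
    genes = m.counts.index
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tagwise, index=genes),
        raw=pd.Series(raw, index=genes),
        shrinkage_weight=float(w_shrink),
    )


def test_generation_effect(
    m: BarcodeCountMatrix,
    d: DispersionEstimates,
    haldane: float = 0.5,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of the generation effect per gene.

    ``log2fc = log2((S1/L1) / (S0/L0))`` from group count sums S and raw
    library-size sums L, with ``haldane`` added to both count sums when
    either is zero.  The standard error propagates the NB variance
    ``mu + phi mu^2`` through the log ratio (delta method); p-values are
    two-sided normal.  Genes with zero counts in both groups are untestable
    and reported with log2fc 0 and p 1.  ``lib_sizes`` defaults to the raw
    column totals.

    Returns a DataFrame indexed by gene with columns log2fc, se, p_value,
    untestable.
    """
    cols0, cols1 = _group_columns(m)
    lib = (m.counts.sum(axis=0) if lib_sizes is None else lib_sizes).astype(float)
    phi = d.tagwise.to_numpy(float)

    out = {}
    parts = []
    for cols in (cols0, cols1):
        S = m.counts[cols].sum(axis=1).to_numpy(float)
        L = float(lib[cols].sum())
        sumsq = float((lib[cols] ** 2).sum())
        parts.append((S, L, sumsq))
    (S0, L0, q0), (S1, L1, q1) = parts
    untestable = (S0 == 0) & (S1 == 0)
    zero = (S0 == 0) | (S1 == 0)
    S0c = S0 + haldane * zero
    S1c = S1 + haldane * zero
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((S1c / L1) / (S0c / L0))
        var_ln = (1.0 / S0c + phi * q0 / L0**2) + (1.0 / S1c + phi * q1 / L1**2)
    se = np.sqrt(var_ln) / LN2
    with np.errstate(invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc[untestable] = 0.0
    p[untestable] = 1.0
    se[untestable] = np.nan
    return pd.DataFrame(
        {"log2fc": log2fc, "se": se, "p_value": np.clip(p, 0.0, 1.0),
         "untestable": untestable},
        index=m.counts.index,
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q(i) = min_{j >= i} p_(j) * m / j`` on the ascending order statistics,
    capped at 1 and returned in the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def fit_strain(
    m: BarcodeCountMatrix,
    strain: str,
    prior_n: float = 10.0,
    haldane: float = 0.5,
) -> pd.DataFrame:
    """Dispersion estimation + generation test + BH FDR for one strain."""
    sub = m.subset_strain(strain)
    disp = estimate_dispersions(sub, prior_n=prior_n)
    res = test_generation_effect(sub, disp, haldane=haldane)
    res["fdr"] = adjust_bh(res["p_value"].to_numpy())
    return res
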