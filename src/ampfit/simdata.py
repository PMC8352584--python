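"""Synthetic pooled-screen generator with ground truth.

The generator emulates the statistical structure of a multi-strain pooled
overexpression Bar-seq experiment: ~4,900 barcoded genes assayed in a panel
of strains with 2-3 biological replicates at generations 0 and 10, starting
abundances drawn from a Dirichlet, per-gene true log2 fitness effects that
tilt end-point abundances, negative-binomial counts with library-size
variation, and end-point dropout of strongly depleted barcodes.  A planted
set of genes deleterious across the whole panel (with strong, gene-
intrinsic effects) plus per-strain private effects provide ground truth for
recovery testing, and co-generated annotations embed a term enriched among
the planted genes with a configurable odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import GrowthCurve, QpcrMeasurement
from .io import BarcodeCountMatrix, GeneAnnotation

PLANTED_TERM = "dosage_sensitive_module"


@dataclass
class StrainSim:
    """Per-strain simulation settings."""

    name: str
    n_replicates: int = 3
    sensitivity: float = 1.0     # global multiplier on all true effects
    effect_fraction: float = 0.2  # fraction of genes with a true effect

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError(f"strain {self.name}: n_replicates must be >= 2")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError(f"strain {self.name}: effect_fraction outside [0,1]")
        if self.sensitivity <= 0:
            raise ValueError(f"strain {self.name}: sensitivity must be > 0")


def default_strains(n: int = 15) -> list[StrainSim]:
    """Panel of n strains; the last two carry duplicates only, the rest
    triplicates, mirroring a realistic panel."""
    out = []
    for i in range(n):
        reps = 2 if i >= n - 2 else 3
        out.append(StrainSim(name=f"strain{i + 1:02d}", n_replicates=reps))
    return out


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_experiment`.

    Effects are total log2 abundance changes over the 10-generation
    competition.  Private per-strain effects draw magnitudes uniformly from
    ``effect_size_range`` with ``beneficial_fraction`` positive; the shared
    (commonly deleterious) gene set draws one strong deleterious effect per
    gene from ``common_effect_range``, applied in every strain scaled by its
    sensitivity.
    """

    seed: int
    n_genes: int = 4871
    strains: list = field(default_factory=default_strains)
    effect_size_range: tuple = (0.5, 2.5)
    beneficial_fraction: float = 0.3
    commonly_deleterious_fraction: float = 0.3  # of a strain's effect genes
    common_effect_range: tuple = (1.5, 2.5)
    dispersion: float = 0.1
    library_size_median: float = 7.5e6
    library_size_sigma: float = 0.25
    dirichlet_alpha: float = 5.0
    dropout_rate: float = 0.5
    dropout_threshold_cpm: float = 20.0
    count_model: str = "nb"          # "nb" | "lognormal" (model-mismatch option)
    generations: tuple = (0, 10)
    # annotation co-generation
    n_random_terms: int = 20
    term_size_range: tuple = (80, 300)
    planted_term_size: int = 150
    planted_term_odds: float = 20.0  # odds ratio favouring planted common genes

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("beneficial_fraction", "commonly_deleterious_fraction",
                     "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.count_model not in ("nb", "lognormal"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if not self.strains:
            raise ValueError("need at least one strain")


@dataclass
class SimTruth:
    """Ground truth aligned with the emitted count matrix."""

    effects: pd.DataFrame          # genes x strains true log2 effects
    common_genes: set              # planted panel-wide deleterious set
    private_genes: dict            # strain -> set of private effect genes
    planted_term: str
    term_sets: dict                # term -> gene set (as written to annotations)


def _sample_counts(rng, mean: np.ndarray, phi: float, model: str) -> np.ndarray:
    if model == "lognormal" and phi > 0:
        # moment-matched multiplicative noise then Poisson sampling
        sigma2 = np.log1p(phi)
        noisy = mean * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), mean.shape)
        return rng.poisson(noisy)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[BarcodeCountMatrix, SimTruth, list]:
    """Generate counts, ground truth and annotations for one experiment.

    Per strain: starting relative abundances are Dirichlet; end-point
    abundances are the starting ones tilted by ``2**effect`` and
    renormalized; counts are NB(mean = abundance x library size, dispersion
    phi) with log-normal library sizes; end-point barcodes whose expected
    abundance falls below ``dropout_threshold_cpm`` are zeroed with
    probability ``dropout_rate`` and flagged missing.  Identical config and
    seed give byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    genes = pd.Index([f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)],
                     name="gene_id")
    strains = cfg.strains
    n_eff_mean = np.mean([s.effect_fraction for s in strains]) * cfg.n_genes
    n_common = int(round(cfg.commonly_deleterious_fraction * n_eff_mean))
    n_common = min(n_common, cfg.n_genes)
    common_idx = rng.choice(cfg.n_genes, size=n_common, replace=False)
    common_mag = rng.uniform(*cfg.common_effect_range, size=n_common)

    effects = pd.DataFrame(0.0, index=genes, columns=[s.name for s in strains])
    private_genes: dict = {}
    non_common = np.setdiff1d(np.arange(cfg.n_genes), common_idx)
    for s in strains:
        effects.iloc[common_idx, effects.columns.get_loc(s.name)] = (
            -common_mag * s.sensitivity
        )
        n_eff = int(round(s.effect_fraction * cfg.n_genes))
        n_priv = max(0, n_eff - n_common)
        priv_idx = rng.choice(non_common, size=min(n_priv, non_common.size),
                              replace=False)
        mag = rng.uniform(*cfg.effect_size_range, size=priv_idx.size)
        sign = np.where(rng.random(priv_idx.size) < cfg.beneficial_fraction,
                        1.0, -1.0)
        effects.iloc[priv_idx, effects.columns.get_loc(s.name)] = (
            sign * mag * s.sensitivity
        )
        private_genes[s.name] = set(genes[priv_idx])

    g0, g1 = cfg.generations
    counts = {}
    missing = {}
    rows = []
    for s in strains:
        p0 = rng.dirichlet(np.full(cfg.n_genes, cfg.dirichlet_alpha))
        tilt = p0 * np.exp2(effects[s.name].to_numpy())
        p1 = tilt / tilt.sum()
        for rep in range(1, s.n_replicates + 1):
            for gen, p in ((g0, p0), (g1, p1)):
                lib = rng.lognormal(np.log(cfg.library_size_median),
                                    cfg.library_size_sigma)
                y = _sample_counts(rng, p * lib, cfg.dispersion, cfg.count_model)
                miss = np.zeros(cfg.n_genes, dtype=bool)
                if gen == g1 and cfg.dropout_rate > 0:
                    eligible = p * 1e6 < cfg.dropout_threshold_cpm
                    drop = eligible & (rng.random(cfg.n_genes) < cfg.dropout_rate)
                    y = np.where(drop, 0, y)
                    miss = drop
                sid = f"{s.name}_r{rep}_g{gen}"
                counts[sid] = y.astype(np.int64)
                missing[sid] = miss
                rows.append({"sample_id": sid, "strain": s.name,
                             "replicate": rep, "generation": gen})

    samples = pd.DataFrame(rows).set_index("sample_id")
    matrix = BarcodeCountMatrix(
        counts=pd.DataFrame(counts, index=genes),
        samples=samples,
        missing=pd.DataFrame(missing, index=genes),
    )
    common_genes = set(genes[common_idx])
    term_sets = _generate_terms(rng, genes, common_idx, cfg)
    annotations = _generate_annotations(rng, genes, common_genes, term_sets)
    truth = SimTruth(
        effects=effects,
        common_genes=common_genes,
        private_genes=private_genes,
        planted_term=PLANTED_TERM,
        term_sets=term_sets,
    )
    return matrix, truth, annotations


def _generate_terms(rng, genes, common_idx, cfg: SimulationConfig) -> dict:
    n = len(genes)
    weights = np.ones(n)
    weights[common_idx] = cfg.planted_term_odds
    planted = rng.choice(
        n, size=min(cfg.planted_term_size, n), replace=False,
        p=weights / weights.sum(),
    )
    term_sets = {PLANTED_TERM: set(genes[planted])}
    lo, hi = cfg.term_size_range
    for i in range(cfg.n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n, size=min(size, n), replace=False)
        term_sets[f"term{i + 1:02d}"] = set(genes[members])
    return term_sets


def _generate_annotations(rng, genes, common_genes, term_sets) -> list:
    gene_terms: dict = {g: set() for g in genes}
    for term, members in term_sets.items():
        for g in members:
            gene_terms[g].add(term)
    annotations = []
    for g in genes:
        common = g in common_genes
        features = {
            "interaction_count": float(rng.poisson(15 if common else 8)),
            "disorder_score": float(rng.beta(2, 4) if common else rng.beta(2, 7)),
            "trp_fraction": float(rng.beta(2, 150)),
            "nonsyn_snps": float(rng.poisson(3 if common else 6)),
        }
        flags = {
            "essential": bool(rng.random() < (0.25 if common else 0.15)),
            "complex_member": bool(rng.random() < (0.4 if common else 0.25)),
            "translation": bool(rng.random() < (0.15 if common else 0.04)),
        }
        annotations.append(
            GeneAnnotation(g, frozenset(gene_terms[g]), features, flags)
        )
    return annotations


def simulate_qpcr(
    copy: float,
    control_copy: float,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
    efficiency: float = 2.0,
    n_technical: int = 3,
    base_ct_reference: float = 20.0,
) -> tuple[QpcrMeasurement, QpcrMeasurement]:
    """Simulate Ct values for a strain of given plasmid copy number and a
    control strain of known copy number.

    At zero noise the delta-Ct chain is exactly invertible:
    ``copy_number(qpcr_ratio(strain), qpcr_ratio(control), control_copy)``
    returns ``copy``.
    """
    if copy <= 0 or control_copy <= 0:
        raise ValueError("copy numbers must be positive")
    rng = np.random.default_rng(seed)

    def measure(name: str, copies: float) -> QpcrMeasurement:
        shift = np.log(copies) / np.log(efficiency)
        ct_ref = base_ct_reference + rng.normal(0, noise_sd_ct, n_technical)
        ct_tgt = base_ct_reference - shift + rng.normal(0, noise_sd_ct, n_technical)
        return QpcrMeasurement(name, list(ct_tgt), list(ct_ref), efficiency)

    return measure("strain", copy), measure("control", control_copy)


def simulate_growth(
    doubling_h: float,
    noise: float = 0.0,
    seed: int = 0,
    od_start: float = 0.05,
    od_end: float = 0.5,
    n_points: int = 12,
) -> GrowthCurve:
    """Exponential OD600 series through the fit window with multiplicative
    log-normal noise of the given relative magnitude."""
    if doubling_h <= 0:
        raise ValueError("doubling time must be positive")
    if n_points < 3:
        raise ValueError("need >= 3 time points")
    rng = np.random.default_rng(seed)
    t_end = doubling_h * np.log2(od_end / od_start)
    times = np.linspace(0.0, t_end, n_points)
    od = od_start * np.exp2(times / doubling_h)
    if noise > 0:
        od = od * np.exp(rng.normal(0.0, noise, n_points))
    return GrowthCurve(times=times, od=od, fit_window=(od_start / 2, od_end * 2))
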