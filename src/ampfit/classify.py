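"""Gene-set taxonomy over per-strain significance calls.

From the per-(gene, strain) fitness table this module derives the sets the
screen analysis reasons about: per-strain deleterious/beneficial genes
(FDR < 0.05 with the sign of the abundance change), genes commonly
deleterious across the strain panel (deleterious in at least 66% of
strains), strain-specific gene lists (significant in a focal strain and at
most ``max_others`` other strains), enrichment backgrounds of confidently
insignificant genes, and the histogram of genes by number of strains hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class StrainGeneSets:
    """Per-strain significant gene sets from the fitness table."""

    deleterious: dict[str, set] = field(default_factory=dict)
    beneficial: dict[str, set] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.deleterious)

    def significant(self, strain: str) -> set:
        """Genes significant in either direction in one strain."""
        return self.deleterious[strain] | self.beneficial[strain]


def call_directions(
    table: pd.DataFrame, fdr_threshold: float = 0.05
) -> StrainGeneSets:
    """Split significant genes by the sign of the estimated log2 change.

    Deleterious: fdr < threshold and log2fc < 0 (plasmid depleted).
    Beneficial: fdr < threshold and log2fc > 0.  A significant gene with
    log2fc exactly 0 is called neither.
    """
    sets = StrainGeneSets()
    for strain, sub in table.groupby("strain", sort=False):
        sig = sub["fdr"] < fdr_threshold
        sets.deleterious[strain] = set(sub.loc[sig & (sub["log2fc"] < 0), "gene_id"])
        sets.beneficial[strain] = set(sub.loc[sig & (sub["log2fc"] > 0), "gene_id"])
    return sets


def annotate_directions(
    table: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Return a copy of the table with a direction column filled in."""
    sets = call_directions(table, fdr_threshold)
    out = table.copy()
    direction = []
    for gene, strain in zip(out["gene_id"], out["strain"]):
        if gene in sets.deleterious[strain]:
            direction.append("deleterious")
        elif gene in sets.beneficial[strain]:
            direction.append("beneficial")
        else:
            direction.append("none")
    out["direction"] = direction
    return out


def strain_count_threshold(n_strains: int, fraction: float = 0.66) -> int:
    """Minimum number of strains for a 'commonly deleterious' call:
    ``ceil(fraction * n_strains)``; with 15 strains and 66% this is 10."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if n_strains < 1:
        raise ValueError("need at least one strain")
    return math.ceil(fraction * n_strains)


def commonly_deleterious(sets: StrainGeneSets, fraction: float = 0.66) -> set:
    """Genes deleterious in at least ``ceil(fraction * n_strains)`` strains."""
    k_min = strain_count_threshold(len(sets.strains), fraction)
    counts: dict = {}
    for strain in sets.strains:
        for g in sets.deleterious[strain]:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, k in counts.items() if k >= k_min}


def strain_specific(
    sets: StrainGeneSets,
    max_others: int = 2,
    direction: str | None = None,
) -> dict[str, set]:
    """Per-strain lists of genes significant in the focal strain and in at
    most ``max_others`` other strains.

    ``direction`` None counts significance in either direction (default);
    "deleterious"/"beneficial" restrict both the focal and the other-strain
    tallies to that direction.
    """
    if direction is None:
        members = {s: sets.significant(s) for s in sets.strains}
    elif direction == "deleterious":
        members = dict(sets.deleterious)
    elif direction == "beneficial":
        members = dict(sets.beneficial)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    counts: dict = {}
    for s in sets.strains:
        for g in members[s]:
            counts[g] = counts.get(g, 0) + 1
    return {
        s: {g for g in members[s] if counts[g] - 1 <= max_others}
        for s in sets.strains
    }


def strain_background(
    table: pd.DataFrame,
    strain: str,
    fdr_above: float = 0.1,
    min_replicates: int = 2,
) -> set:
    """Enrichment background for a strain-specific query: genes confidently
    insignificant there (fdr > ``fdr_above``) and scored in at least
    ``min_replicates`` biological replicates."""
    sub = table[table["strain"] == strain]
    if sub.empty:
        raise KeyError(f"no rows for strain {strain!r}")
    keep = (sub["fdr"] > fdr_above) & (
        sub["n_replicates_measured"] >= min_replicates
    )
    bg = set(sub.loc[keep, "gene_id"])
    if not bg:
        raise ValueError(f"strain {strain!r}: empty enrichment background")
    return bg


def measured_background(table: pd.DataFrame, min_replicates: int = 1) -> set:
    """Panel-wide background: genes measured in >= ``min_replicates``
    replicates in at least one strain."""
    keep = table["n_replicates_measured"] >= min_replicates
    return set(table.loc[keep, "gene_id"])


def strain_count_histogram(sets: StrainGeneSets) -> dict[int, int]:
    """Number of genes deleterious in exactly k strains, for each k >= 1.

    The histogram partitions the union of the per-strain deleterious sets:
    its values sum to the number of genes deleterious somewhere.
    """
    counts: dict = {}
    for strain in sets.strains:
        for g in sets.deleterious[strain]:
            counts[g] = counts.get(g, 0) + 1
    hist: dict[int, int] = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))
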