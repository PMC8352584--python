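"""Readers/writers for the tabular formats used throughout the pipeline.

All files are plain UTF-8 TSV; lines starting with ``#`` are comments.
Counts files carry one gene per row and one sequencing sample per column.
Cells that were empty or ``NA`` at load time are folded to 0 and recorded
in a boolean missing mask so that downstream imputation can distinguish an
absent barcode from a barcode that was never eligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKENS = ("", "NA")

#: annotation columns interpreted as boolean flags rather than numeric features
DEFAULT_FLAG_COLUMNS = ("essential", "complex_member", "translation")

SAMPLE_SHEET_COLUMNS = ("sample_id", "strain", "replicate", "generation")

#: column prefix for per-replicate fitness scores in the fitness table TSV
REP_SCORE_PREFIX = "score_rep"


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing sample of the pooled screen."""

    sample_id: str
    strain: str
    replicate: int
    generation: int


@dataclass
class BarcodeCountMatrix:
    """Integer barcode counts (genes x samples) with sample metadata.

    Attributes
    ----------
    counts : DataFrame, index gene_id, columns sample_id, integer dtype
    samples : DataFrame indexed by sample_id with columns strain,
        replicate, generation
    missing : boolean DataFrame aligned with ``counts``; True where the
        input cell was absent (empty / NA) rather than an observed count
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    missing: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = pd.DataFrame(
                False, index=self.counts.index, columns=self.counts.columns
            )
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.samples["strain"]))

    @property
    def generations(self) -> tuple[int, int]:
        """(start, end) generation labels present in the sample sheet."""
        gens = sorted(set(int(g) for g in self.samples["generation"]))
        return gens[0], gens[-1]

    def sample_meta(self) -> list[SampleMeta]:
        return [
            SampleMeta(str(sid), str(r.strain), int(r.replicate), int(r.generation))
            for sid, r in self.samples.iterrows()
        ]

    def subset_strain(self, strain: str) -> "BarcodeCountMatrix":
        keep = self.samples.index[self.samples["strain"] == strain]
        if len(keep) == 0:
            raise KeyError(f"no samples for strain {strain!r}")
        return BarcodeCountMatrix(
            counts=self.counts[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            missing=self.missing[keep].copy(),
        )

    def copy(self) -> "BarcodeCountMatrix":
        return BarcodeCountMatrix(
            self.counts.copy(), self.samples.copy(), self.missing.copy()
        )

    def replicate_pairs(self, strain: str) -> list[tuple[int, str, str]]:
        """(replicate, gen-start sample, gen-end sample) triples for a strain."""
        g0, g1 = self.generations
        sub = self.samples[self.samples["strain"] == strain]
        out = []
        for rep in sorted(set(int(r) for r in sub["replicate"])):
            s0 = sub.index[(sub["replicate"] == rep) & (sub["generation"] == g0)]
            s1 = sub.index[(sub["replicate"] == rep) & (sub["generation"] == g1)]
            out.append((rep, s0[0], s1[0]))
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if list(self.counts.columns) != list(self.samples.index):
            in_counts = set(self.counts.columns) - set(self.samples.index)
            in_sheet = set(self.samples.index) - set(self.counts.columns)
            raise FormatError(
                "counts columns and sample sheet disagree: "
                f"only in counts {sorted(in_counts)}, only in sheet {sorted(in_sheet)}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count for gene {self.counts.index[g]!r} "
                f"in sample {self.counts.columns[s]!r}"
            )
        validate_sample_sheet(self.samples)


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    """Enforce the pairing invariants of the competitive-growth design.

    Every (strain, replicate) present at the starting generation must have a
    partner at the end generation and vice versa, and each strain needs at
    least two replicates.
    """
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    gens = sorted(set(int(g) for g in samples["generation"]))
    if len(gens) != 2:
        raise FormatError(f"expected exactly two generation labels, got {gens}")
    g0, g1 = gens
    for strain, sub in samples.groupby("strain", sort=False):
        pairs0 = {int(r) for r in sub["replicate"][sub["generation"] == g0]}
        pairs1 = {int(r) for r in sub["replicate"][sub["generation"] == g1]}
        if pairs0 != pairs1:
            raise FormatError(
                f"strain {strain!r}: replicates {sorted(pairs0 ^ pairs1)} lack a "
                "generation partner"
            )
        if len(pairs0) < 2:
            raise FormatError(f"strain {strain!r}: fewer than 2 replicates")
        for gen, pairs in ((g0, pairs0), (g1, pairs1)):
            n = ((sub["generation"] == gen)).sum()
            if n != len(pairs):
                raise FormatError(
                    f"strain {strain!r}: duplicated (replicate, generation) entries"
                )
        if (sub["replicate"].astype(int) < 1).any():
            raise FormatError(f"strain {strain!r}: replicate numbers must be >= 1")


def read_counts(path, sample_sheet) -> BarcodeCountMatrix:
    """Load a gene x sample count TSV together with its sample sheet.

    Empty or ``NA`` cells become 0 with the missing mask set.  Negative or
    non-integer counts, duplicate genes, and count/sheet sample mismatches
    are hard errors.
    """
    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        keep_default_na=False, na_values=[],
    )
    if raw.shape[1] < 2:
        raise FormatError("counts file needs a gene_id column and >=1 sample")
    raw = raw.set_index(raw.columns[0])
    missing = raw.isin(MISSING_TOKENS)
    filled = raw.mask(missing, "0")
    numeric = filled.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round())
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-integer count {raw.iat[g, s]!r} for gene {raw.index[g]!r} "
            f"in sample {raw.columns[s]!r}"
        )
    counts = numeric.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        g, s = np.argwhere(counts.to_numpy() < 0)[0]
        raise FormatError(
            f"negative count for gene {counts.index[g]!r} "
            f"in sample {counts.columns[s]!r}"
        )
    samples = read_sample_sheet(sample_sheet)
    samples = samples.reindex(counts.columns)
    if samples.isna().any(axis=None):
        raise FormatError("sample in counts file absent from sample sheet")
    return BarcodeCountMatrix(counts=counts, samples=samples, missing=missing)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing_cols = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"sample sheet lacks columns {sorted(missing_cols)}")
    sheet = sheet.set_index("sample_id")
    try:
        sheet["replicate"] = sheet["replicate"].astype(int)
        sheet["generation"] = sheet["generation"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate/generation: {exc}") from exc
    validate_sample_sheet(sheet)
    return sheet[["strain", "replicate", "generation"]]


def write_counts(m: BarcodeCountMatrix, counts_path, samples_path=None) -> None:
    out = m.counts.astype(object).mask(m.missing, "NA")
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        sheet = m.samples.copy()
        sheet.index.name = "sample_id"
        sheet.to_csv(samples_path, sep="\t")


@dataclass(frozen=True)
class GeneAnnotation:
    """Categorical terms, continuous features and boolean flags for one gene."""

    gene_id: str
    terms: frozenset
    features: dict
    flags: dict

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if not math.isfinite(float(value)):
                raise FormatError(f"{self.gene_id}: feature {name!r} not finite")
            if name.endswith("_fraction") and not 0.0 <= float(value) <= 1.0:
                raise FormatError(
                    f"{self.gene_id}: fraction feature {name!r}={value} outside [0,1]"
                )


_BOOL_TOKENS = {"0": False, "1": True, "false": False, "true": True,
                "False": False, "True": True}


def read_annotations(path, flag_columns=DEFAULT_FLAG_COLUMNS) -> list[GeneAnnotation]:
    """Parse a gene annotation TSV.

    Expected columns: ``gene_id``, ``terms`` (pipe-delimited category ids,
    may be empty), then one column per numeric feature and one per boolean
    flag.  Flag columns are identified by name (``flag_columns``).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        keep_default_na=False, na_values=[],
    )
    if "gene_id" not in df.columns or "terms" not in df.columns:
        raise FormatError("annotation table needs gene_id and terms columns")
    flag_cols = [c for c in df.columns if c in set(flag_columns)]
    feature_cols = [c for c in df.columns if c not in ("gene_id", "terms", *flag_cols)]
    out = []
    for _, row in df.iterrows():
        terms = frozenset(t for t in str(row["terms"]).split("|") if t)
        features = {}
        for c in feature_cols:
            try:
                features[c] = float(row[c])
            except ValueError as exc:
                raise FormatError(
                    f"gene {row['gene_id']!r}: non-numeric value {row[c]!r} "
                    f"in feature column {c!r}"
                ) from exc
        flags = {}
        for c in flag_cols:
            token = str(row[c])
            if token not in _BOOL_TOKENS:
                raise FormatError(
                    f"gene {row['gene_id']!r}: bad boolean {token!r} in {c!r}"
                )
            flags[c] = _BOOL_TOKENS[token]
        out.append(GeneAnnotation(str(row["gene_id"]), terms, features, flags))
    return out


def write_annotations(annotations, path, flag_columns=DEFAULT_FLAG_COLUMNS) -> None:
    feature_names = sorted({k for a in annotations for k in a.features})
    flag_names = [c for c in flag_columns if any(c in a.flags for a in annotations)]
    rows = []
    for a in annotations:
        row = {"gene_id": a.gene_id, "terms": "|".join(sorted(a.terms))}
        row.update({k: repr(a.features[k]) for k in feature_names})
        row.update({k: int(a.flags.get(k, False)) for k in flag_names})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def term_sets(annotations) -> dict:
    """term -> set of gene ids carrying it."""
    out: dict = {}
    for a in annotations:
        for t in a.terms:
            out.setdefault(t, set()).add(a.gene_id)
    return out


def feature_values(annotations, name: str) -> dict:
    """gene_id -> feature value, restricted to genes where it is present."""
    return {a.gene_id: a.features[name] for a in annotations if name in a.features}


# -- fitness table ---------------------------------------------------------

FITNESS_FIXED_COLUMNS = (
    "gene_id", "strain", "mean_score", "n_replicates_measured", "imputed",
    "log2fc", "se", "p_value", "fdr", "direction",
)


def write_fitness_table(table: pd.DataFrame, path) -> None:
    """Write a fitness table TSV; floats use repr precision so that
    :func:`read_fitness_table` round-trips finite values bit-exactly."""
    rep_cols = [c for c in table.columns if c.startswith(REP_SCORE_PREFIX)]
    cols = [c for c in FITNESS_FIXED_COLUMNS if c in table.columns] + rep_cols
    out = table[cols].copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda x: "NA" if pd.isna(x) else repr(float(x)))
        elif out[c].dtype.kind == "b":
            out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_fitness_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[])
    rep_cols = [c for c in df.columns if c.startswith(REP_SCORE_PREFIX)]
    float_cols = [c for c in ("mean_score", "log2fc", "se", "p_value", "fdr")
                  if c in df.columns] + rep_cols
    for c in float_cols:
        df[c] = pd.to_numeric(df[c].replace("NA", np.nan))
    if "imputed" in df.columns:
        df["imputed"] = df["imputed"].astype(int).astype(bool)
    if "n_replicates_measured" in df.columns:
        df["n_replicates_measured"] = df["n_replicates_measured"].astype(int)
    return df
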