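"""Auxiliary quantitative assays around the screen.

* qPCR relative quantification: plasmid copy number from the delta-Ct of a
  plasmid marker (KAN role) against a single-copy genomic reference (TUB1
  role), chained through an internal control strain of known copy number.
* RPKM for sequencing-based copy estimates.
* Growth-curve doubling times from a log-linear fit in the exponential
  window, relative growth between paired cultures, and paired t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class QpcrMeasurement:
    """Technical-replicate Ct values for one strain (target and reference)."""

    strain: str
    ct_target: list          # plasmid marker amplicon
    ct_reference: list       # single-copy genomic reference amplicon
    efficiency: float = 2.0  # per-cycle amplification factor, 2.0 = 100%

    def __post_init__(self) -> None:
        if len(self.ct_target) == 0 or len(self.ct_reference) == 0:
            raise ValueError("need >= 1 technical replicate for each amplicon")
        for ct in (*self.ct_target, *self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"Ct value {ct} outside (0, 45)")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")


@dataclass
class GrowthCurve:
    """An OD600 time series with the window used for the exponential fit."""

    times: np.ndarray                  # hours, strictly increasing
    od: np.ndarray                     # positive OD600 readings
    fit_window: tuple = (0.05, 0.5)    # OD range treated as log phase

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.od = np.asarray(self.od, float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-d and aligned")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.od > 0):
            raise ValueError("OD values must be positive")

    def window_points(self) -> np.ndarray:
        lo, hi = self.fit_window
        return (self.od >= lo) & (self.od <= hi)


def qpcr_ratio(m: QpcrMeasurement) -> float:
    """Target/reference abundance ratio ``efficiency ** (mean Ct_ref - mean Ct_target)``.

    Technical replicates are averaged on the Ct scale before the delta.
    """
    delta = float(np.mean(m.ct_reference)) - float(np.mean(m.ct_target))
    return float(m.efficiency**delta)


def copy_number(strain_ratio: float, control_ratio: float, control_copy: float) -> float:
    """Scale a strain's marker/reference ratio to absolute copies via an
    internal control of known copy number."""
    if control_ratio <= 0 or control_copy <= 0:
        raise ValueError("control ratio and copy number must be positive")
    return strain_ratio / control_ratio * control_copy


def rpkm(read_count: int, gene_length_bp: int, total_reads: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if gene_length_bp <= 0 or total_reads <= 0:
        raise ValueError("gene length and total reads must be positive")
    if read_count < 0:
        raise ValueError("read count must be >= 0")
    return read_count * 1e9 / (gene_length_bp * total_reads)


def doubling_time(c: GrowthCurve) -> float:
    """Doubling time (h) from a least-squares fit of log2(OD) vs time over
    the points inside the fit window; requires >= 3 window points and a
    positive slope."""
    keep = c.window_points()
    if keep.sum() < 3:
        raise ValueError("need >= 3 points inside the fit window")
    slope, _ = np.polyfit(c.times[keep], np.log2(c.od[keep]), 1)
    if slope <= 0:
        raise ValueError("no exponential growth detected (non-positive slope)")
    return float(1.0 / slope)


@dataclass
class TTestResult:
    t: float
    p_value: float
    df: int
    degenerate: bool = False


def paired_ttest(a, b, sides: str = "two", direction: str = "less") -> TTestResult:
    """Paired t-test on differences d = a - b.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with n-1 degrees of freedom.  For
    ``sides="one"``, ``direction`` names the alternative for mean(d):
    "less" or "greater".  Zero-variance differences are degenerate: p = 0
    for a nonzero mean (the data are perfectly one-sided), p = 1 otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length 1-d samples with n >= 2")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    d = a - b
    n = d.size
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p_value=1.0, df=df, degenerate=True)
        return TTestResult(
            t=math.copysign(math.inf, mean), p_value=0.0, df=df, degenerate=True
        )
    t = mean / (sd / math.sqrt(n))
    if sides == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif direction == "less":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(stats.t.sf(t, df))
    return TTestResult(t=float(t), p_value=min(1.0, p), df=df)


def relative_growth(test_curves, control_curves) -> dict:
    """Per-replicate doubling-time ratios test/control with mean and sd.

    Curves must be paired by replicate; mismatched counts are an error.
    """
    if len(test_curves) != len(control_curves):
        raise ValueError("mismatched replicate counts")
    if len(test_curves) == 0:
        raise ValueError("need >= 1 replicate pair")
    ratios = np.array(
        [doubling_time(t) / doubling_time(c)
         for t, c in zip(test_curves, control_curves)]
    )
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else float("nan"),
    }
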