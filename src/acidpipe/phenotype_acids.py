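"""Organic-acid statistics: two-sample t-tests on raw or summary data,
mean +/- SD tables, 2^-ddCt relative expression, and FPKM-vs-qPCR validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AcidMeasurements",
    "TestResult",
    "two_sample_ttest",
    "summarize_acids",
    "ddct_relative_expression",
    "validation_pcc",
    "load_acid_reference_table",
]

ACIDS = ("OA", "MA", "CA")


@dataclass(frozen=True)
class AcidMeasurements:
    """One (acid, variety, stage) cell, as raw replicate values or mean/sd/n."""

    acid: str
    variety: str
    stage: str
    values: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.acid not in ACIDS:
            raise ValueError(f"unknown acid {self.acid!r}")
        if self.values is None and (self.mean is None or self.sd is None or self.n is None):
            raise ValueError("need either raw values or (mean, sd, n)")
        if self.values is not None and any(v < 0 for v in self.values):
            raise ValueError("acid contents must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def summary(self) -> tuple[float, float, int]:
        if self.values is not None:
            arr = np.asarray(self.values, dtype=float)
            if len(arr) < 2:
                raise ValueError("need >= 2 replicates")
            return float(arr.mean()), float(arr.std(ddof=1)), len(arr)
        return float(self.mean), float(self.sd), int(self.n)


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    label: str  # ns / * / **

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0,1]")


def _label(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def two_sample_ttest(a: AcidMeasurements, b: AcidMeasurements, mode: str = "student") -> TestResult:
    """Two-sided two-sample t-test.

    ``student`` pools variances (df = n_a + n_b - 2); ``welch`` uses the
    Satterthwaite approximation.  Works directly from summary statistics so
    printed mean +/- SD tables are testable.
    """
    if mode not in ("student", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    if a.acid != b.acid or a.stage != b.stage:
        raise ValueError("groups must share acid and stage")
    m1, s1, n1 = a.summary
    m2, s2, n2 = b.summary
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if s1 == 0 and s2 == 0:
        df = n1 + n2 - 2 if mode == "student" else float(n1 + n2 - 2)
        if m1 == m2:
            return TestResult(t=0.0, df=float(df), p=1.0, label="ns")
        return TestResult(t=math.copysign(math.inf, m1 - m2), df=float(df), p=0.0, label="**")
    t, p = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=(mode == "student")
    )
    if mode == "student":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TestResult(t=float(t), df=df, p=float(p), label=_label(float(p)))


def summarize_acids(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw replicates into a per-(acid, variety, stage) mean +/- SD table.

    ``raw`` columns: acid, variety, stage, value.
    """
    required = {"acid", "variety", "stage", "value"}
    if not required <= set(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(required)}")
    grouped = raw.groupby(["acid", "variety", "stage"])["value"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with <2 replicates: {bad}")
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["n"] = out["n"].astype(int)
    return out


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by 2^-ddCt against a reference gene and calibrator."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class PccResult:
    r: float
    p: float
    defined: bool


def validation_pcc(fpkm_series, qpcr_series) -> PccResult:
    """Pearson correlation between matched FPKM and qPCR profiles."""
    x = np.asarray(fpkm_series, dtype=float)
    y = np.asarray(qpcr_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PccResult(r=float("nan"), p=float("nan"), defined=False)
    r, p = stats.pearsonr(x, y)
    return PccResult(r=float(r), p=float(p), defined=True)


def load_acid_reference_table() -> pd.DataFrame:
    """Packaged mean +/- SD acid-content table (mg/g FW, n = 3 per cell)."""
    with resources.files("acidpipe.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
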