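"""Diagnostic test performance and paired-comparison statistics.

Per-modality 2x2 confusion counts yield sensitivity, specificity,
predictive values and accuracy with exact (Clopper-Pearson) confidence
intervals.  Modalities read on the same patients are compared with
Cochran's Q on per-patient correctness indicators, McNemar's test as the
pairwise post hoc, and Cohen's kappa for inter-reading agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "Proportion",
    "DiagnosticAccuracy",
    "PairedReadings",
    "accuracy_from_counts",
    "cochran_q",
    "mcnemar",
    "cohen_kappa",
    "TestResult",
]


class DiagnosticsError(ValueError):
    """Invalid diagnostic inputs (empty tables, mismatched vectors...)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level 2x2 counts against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DiagnosticsError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Number of truth-positive patients."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_calls(cls, truth: Sequence[int], calls: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(truth, dtype=bool)
        c = np.asarray(calls, dtype=bool)
        if t.shape != c.shape:
            raise DiagnosticsError("truth and calls must have equal length")
        return cls(
            tp=int(np.sum(t & c)),
            fp=int(np.sum(~t & c)),
            fn=int(np.sum(t & ~c)),
            tn=int(np.sum(~t & ~c)),
        )


@dataclass(frozen=True)
class Proportion:
    """A point estimate with its exact 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Se/Sp/PPV/NPV/accuracy; predictive values are None when undefined."""

    se: Proportion
    sp: Proportion
    ppv: Optional[Proportion]
    npv: Optional[Proportion]
    acc: Proportion


def _proportion(k: int, n: int, alpha: float = 0.05) -> Optional[Proportion]:
    if n == 0:
        return None
    low, high = proportion_confint(k, n, alpha=alpha, method="beta")
    return Proportion(k / n, float(low), float(high), k, n)


def accuracy_from_counts(c: ConfusionCounts, alpha: float = 0.05) -> DiagnosticAccuracy:
    """Point estimates and Clopper-Pearson intervals from 2x2 counts.

    Requires at least one truth-positive and one truth-negative patient.
    PPV/NPV with empty denominators (no positive or no negative calls) are
    reported as ``None`` rather than zero.
    """
    if c.n == 0:
        raise DiagnosticsError("all-zero confusion counts")
    if c.n_positive == 0 or c.n_negative == 0:
        raise DiagnosticsError(
            "sensitivity/specificity need at least one positive and one "
            f"negative truth patient (got {c.n_positive}/{c.n_negative})"
        )
    return DiagnosticAccuracy(
        se=_proportion(c.tp, c.n_positive, alpha),
        sp=_proportion(c.tn, c.n_negative, alpha),
        ppv=_proportion(c.tp, c.tp + c.fp, alpha),
        npv=_proportion(c.tn, c.tn + c.fn, alpha),
        acc=_proportion(c.tp + c.tn, c.n, alpha),
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[int] = None
    method: str = ""


class PairedReadings:
    """Per-patient truth status and binary calls per (modality, reading).

    Wraps a table with columns ``patient_id``, ``truth`` and one
    ``call_<modality>_<reading>`` column per test arm.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"patient_id", "truth"}
        missing = required - set(frame.columns)
        if missing:
            raise DiagnosticsError(f"readings table missing columns {sorted(missing)}")
        call_cols = [c for c in frame.columns if c.startswith("call_")]
        if not call_cols:
            raise DiagnosticsError("readings table has no call_<modality>_<reading> columns")
        for col in ["truth", *call_cols]:
            vals = set(pd.unique(frame[col]))
            if not vals <= {0, 1, True, False}:
                raise DiagnosticsError(f"column {col!r} must be binary, found {vals}")
        if frame[call_cols].isna().any().any() or frame["truth"].isna().any():
            raise DiagnosticsError("every patient needs a truth value and all calls")
        self.frame = frame.reset_index(drop=True)
        self.call_columns = call_cols

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def modalities(self) -> list[str]:
        return sorted({c.split("_")[1] for c in self.call_columns})

    @property
    def readings(self) -> list[str]:
        return sorted({c.split("_", 2)[2] for c in self.call_columns})

    def truth(self) -> np.ndarray:
        return self.frame["truth"].to_numpy(dtype=int)

    def calls(self, modality: str, reading: str) -> np.ndarray:
        col = f"call_{modality}_{reading}"
        if col not in self.frame.columns:
            raise DiagnosticsError(f"no calls for modality {modality!r}, reading {reading!r}")
        return self.frame[col].to_numpy(dtype=int)

    def confusion(self, modality: str, reading: str) -> ConfusionCounts:
        return ConfusionCounts.from_calls(self.truth(), self.calls(modality, reading))

    def correctness(self, reading: str) -> pd.DataFrame:
        """Per-patient indicator of call == truth, one column per modality."""
        t = self.truth()
        data = {m: (self.calls(m, reading) == t).astype(int) for m in self.modalities}
        return pd.DataFrame(data)

    @classmethod
    def read(cls, path: Union[str, Path]) -> "PairedReadings":
        return cls(pd.read_csv(path, sep=None, engine="python"))

    def write(self, path: Union[str, Path], sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def cochran_q(readings: PairedReadings, reading: str) -> TestResult:
    """Cochran's Q on correctness indicators across >= 3 modalities.

    ``Q = k(k-1) * sum_j (C_j - Cbar)^2 / (k * sum_i R_i - sum_i R_i^2)``
    with ``k`` modalities, column totals ``C_j`` and row totals ``R_i``;
    p-value from chi-square with ``k - 1`` degrees of freedom.  A zero
    denominator (all rows concordant) reports Q = 0, p = 1.
    """
    x = readings.correctness(reading).to_numpy()
    n, k = x.shape
    if k < 2:
        raise DiagnosticsError(f"Cochran's Q needs >= 2 modalities, got {k}")
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - np.sum(row**2)
    if denom == 0:
        return TestResult(0.0, 1.0, df=k - 1, method="cochran-q")
    q = k * (k - 1) * np.sum((col - col.mean()) ** 2) / denom
    p = float(stats.chi2.sf(q, k - 1))
    return TestResult(float(q), p, df=k - 1, method="cochran-q")


def mcnemar(
    a: Sequence[int],
    b: Sequence[int],
    exact: str = "auto",
    exact_threshold: int = 25,
) -> TestResult:
    """McNemar's test on two paired binary vectors.

    ``exact`` is one of ``"auto"`` (exact binomial when the discordant
    total is below ``exact_threshold``), ``"always"`` or ``"never"``.  The
    chi-square form uses no continuity correction.  With no discordant
    pairs, p = 1 by convention.
    """
    av = np.asarray(a, dtype=int)
    bv = np.asarray(b, dtype=int)
    if av.shape != bv.shape:
        raise DiagnosticsError("paired vectors must have equal length")
    b01 = int(np.sum((av == 0) & (bv == 1)))
    b10 = int(np.sum((av == 1) & (bv == 0)))
    nd = b01 + b10
    if nd == 0:
        return TestResult(0.0, 1.0, method="mcnemar-degenerate")
    use_exact = exact == "always" or (exact == "auto" and nd < exact_threshold)
    if use_exact:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b01, b10), nd, 0.5)))
        return TestResult(float(min(b01, b10)), p, method="mcnemar-exact")
    chi2 = (b01 - b10) ** 2 / nd
    return TestResult(float(chi2), float(stats.chi2.sf(chi2, 1)), df=1, method="mcnemar-chi2")


def cohen_kappa(r1: Sequence[int], r2: Sequence[int]) -> float:
    """Cohen's kappa for two binary raters.

    ``kappa = (p_o - p_e) / (1 - p_e)``.  When both raters are constant and
    identical (``p_e = 1``) kappa is reported as 1 by convention.
    """
    x = np.asarray(r1, dtype=int)
    y = np.asarray(r2, dtype=int)
    if x.shape != y.shape or x.size == 0:
        raise DiagnosticsError("rater vectors must be equal-length and non-empty")
    n = x.size
    po = float(np.mean(x == y))
    pe = 0.0
    for cat in (0, 1):
        pe += float(np.mean(x == cat)) * float(np.mean(y == cat))
    if math.isclose(pe, 1.0):
        return 1.0
    return (po - pe) / (1.0 - pe)
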