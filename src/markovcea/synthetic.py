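"""Synthetic inputs: trial readings, cost logs and a Gompertz life table.

Everything the pipeline consumes can be generated here, seed-reproducibly,
so the full analysis runs with no external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticsError, PairedReadings
from .lifetable import LifeTable
from .sensitivity import Z95

__all__ = [
    "TrialSpec",
    "DEFAULT_ACCURACIES",
    "generate_trial",
    "generate_cost_log",
    "GompertzSpec",
    "gompertz_life_table",
]

#: (se, sp) per (modality, reading) from the reference trial's patient-based
#: performance table (7 metastatic / 48 non-metastatic patients).
DEFAULT_ACCURACIES: Mapping[tuple[str, str], tuple[float, float]] = {
    ("NaF", "onsite"): (5 / 7, 44 / 48),
    ("NaF", "central"): (6 / 7, 45 / 48),
    ("FCH", "onsite"): (3 / 7, 48 / 48),
    ("FCH", "central"): (4 / 7, 47 / 48),
    ("DWMRI", "onsite"): (4 / 7, 40 / 48),
    ("DWMRI", "central"): (3 / 7, 45 / 48),
}


@dataclass(frozen=True)
class TrialSpec:
    """Specification of a synthetic diagnostic-accuracy trial.

    ``exact_counts`` mode reproduces the implied confusion counts
    deterministically (requires integral counts); ``sampled`` mode draws
    truth and calls independently given truth.
    """

    n_patients: int = 55
    prevalence: float = 7 / 55
    accuracies: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACCURACIES)
    )
    mode: str = "exact_counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact_counts", "sampled"):
            raise ValueError(f"unknown trial mode {self.mode!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        for key, (se, sp) in self.accuracies.items():
            if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
                raise ValueError(f"se/sp for {key} must lie in [0, 1]")


def _exact_int(x: float, what: str) -> int:
    n = round(x)
    if not math.isclose(x, n, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"exact_counts mode needs integral {what}, got {x}")
    return int(n)


def generate_trial(spec: TrialSpec) -> PairedReadings:
    """Build a per-patient readings table for the given trial specification.

    In ``exact_counts`` mode, positives are listed first and calls are
    assigned by a deterministic greedy fill in patient-index order so that
    per-(modality, reading) marginals match the target counts exactly.  The
    joint assignment across modalities is underdetermined by marginals, so
    cross-modality statistics on such data are fixture-dependent.
    """
    n = spec.n_patients
    n_pos = _exact_int(spec.prevalence * n, "positive count") if spec.mode == "exact_counts" else None
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "exact_counts":
        truth = np.zeros(n, dtype=int)
        truth[:n_pos] = 1
    else:
        truth = (rng.random(n) < spec.prevalence).astype(int)

    if truth.sum() == 0 and spec.prevalence > 0:
        # possible in sampled mode at small n; callers checking sensitivity
        # must handle the absent positive class
        pass

    data = {"patient_id": np.arange(1, n + 1), "truth": truth}
    for (modality, reading), (se, sp) in sorted(spec.accuracies.items()):
        calls = np.zeros(n, dtype=int)
        pos_idx = np.flatnonzero(truth == 1)
        neg_idx = np.flatnonzero(truth == 0)
        if spec.mode == "exact_counts":
            tp = _exact_int(se * len(pos_idx), f"TP count for {modality}/{reading}")
            fp = _exact_int((1 - sp) * len(neg_idx), f"FP count for {modality}/{reading}")
            calls[pos_idx[:tp]] = 1
            calls[neg_idx[:fp]] = 1
        else:
            calls[pos_idx] = rng.random(len(pos_idx)) < se
            calls[neg_idx] = rng.random(len(neg_idx)) < (1 - sp)
        data[f"call_{modality}_{reading}"] = calls
    return PairedReadings(pd.DataFrame(data))


def generate_cost_log(
    mean: float,
    ci: tuple[float, float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Gamma-distributed annual costs moment-matched to a mean and 95% CI.

    The SD is taken as ``(hi - lo) / 3.92``; a collapsed interval yields a
    constant log at the mean.
    """
    lo, hi = ci
    if not lo <= mean <= hi:
        raise ValueError(f"CI ({lo}, {hi}) must bracket the mean {mean}")
    if n < 1:
        raise ValueError("n must be >= 1")
    sd = (hi - lo) / Z95
    if sd == 0.0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(seed)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz hazard ``mu(x) = a * exp(b x)`` on an integer age grid.

    The defaults give a residual life expectancy at 70 in the 12-16 year
    range typical of a low-mortality male population -- a test fixture, not
    an estimate for any real country.
    """

    a: float = 2.5e-5
    b: float = 0.095
    start_age: int = 0
    terminal_age: int = 110

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("baseline hazard a must be positive")
        if self.b < 0:
            raise ValueError("log-hazard slope b must be >= 0")
        if not self.start_age < self.terminal_age:
            raise ValueError("start_age must precede terminal_age")

    def hazard(self, age: float) -> float:
        return self.a * math.exp(self.b * age)

    def qx(self, age: float) -> float:
        """``1 - exp(-integral_age^{age+1} mu)`` in closed form."""
        if self.b == 0.0:
            return -math.expm1(-self.a)
        h = (self.a / self.b) * (
            math.exp(self.b * (age + 1)) - math.exp(self.b * age)
        )
        return -math.expm1(-h)


def gompertz_life_table(spec: GompertzSpec) -> LifeTable:
    """Life table with Gompertz annual death probabilities, closed at the top."""
    ages = np.arange(spec.start_age, spec.terminal_age + 1)
    qx = np.array([spec.qx(float(a)) for a in ages])
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)
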