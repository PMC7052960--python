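"""Decision tree + Markov cohort engine.

A cohort of recurrent prostate-cancer patients is allocated by the imaging
decision tree (true/false positives and negatives) and then evolved over
annual cycles through five core health states -- non-metastatic and
metastatic biochemical recurrence (m0/m1 BCR), non-metastatic and
metastatic castration-resistant disease (m0/m1 CRPC) -- plus death and two
misdiagnosis entry states:

``FN_TUNNEL``
    truth-metastatic patients read as negative; they spend one cycle
    believed non-metastatic (m0-BCR rewards) while progressing according to
    the metastatic row, after which the diagnosis is corrected.
``FP_MISDX``
    truth-non-metastatic patients read as positive.  Under the default
    ``fp_policy="persistent-m1"`` they are managed as metastatic for good
    (m1-BCR utility and transitions, configurable annual cost); under
    ``"merge-m0"`` they carry metastatic-management rewards for one cycle
    only and then rejoin the m0-BCR pathway.

Background mortality is age-dependent via a period life table; competing
annual probabilities are combined on the rate scale,
``1 - prod(1 - p_i)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lifetable import LifeTable

__all__ = [
    "HealthState",
    "TransitionParams",
    "UtilitySet",
    "CostSet",
    "ModelConfig",
    "Strategy",
    "CohortTrace",
    "StrategyResult",
    "ValidationResult",
    "prob_to_rate",
    "rate_to_prob",
    "combine_probs",
    "build_transition_row",
    "transition_matrix",
    "initial_allocation",
    "run_markov",
    "run_strategy_set",
    "validate_life_expectancy",
]

_ROW_TOL = 1e-12


class ModelError(ValueError):
    pass


class RenormalizationError(ModelError):
    """A transition row's outflows exceed 1 (e.g. at extreme DSA bounds)."""


class HealthState(IntEnum):
    M0_BCR = 0
    M1_BCR = 1
    M0_CRPC = 2
    M1_CRPC = 3
    DEATH = 4
    FN_TUNNEL = 5
    FP_MISDX = 6


N_STATES = len(HealthState)
_ALIVE = np.ones(N_STATES)
_ALIVE[HealthState.DEATH] = 0.0


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class TransitionParams:
    """Annual disease-transition and excess-death probabilities.

    ``cis`` maps field names to 95% confidence bounds for the parameters
    whose uncertainty is propagated in sensitivity analyses; excess-death
    probabilities have no published interval and are held fixed.
    """

    p_m0bcr_m1bcr: float = 0.0288
    p_m0bcr_m0crpc: float = 0.0279
    p_m0crpc_m1crpc: float = 0.1520
    p_m1bcr_m1crpc: float = 0.2055
    excess_death_m0crpc: float = 0.0413
    excess_death_m1bcr: float = 0.1306
    excess_death_m1crpc: float = 0.2933
    cis: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "p_m0bcr_m1bcr": (0.0279, 0.0297),
            "p_m0bcr_m0crpc": (0.0249, 0.0308),
            "p_m0crpc_m1crpc": (0.1080, 0.1940),
            "p_m1bcr_m1crpc": (0.1813, 0.2251),
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "p_m0bcr_m1bcr",
            "p_m0bcr_m0crpc",
            "p_m0crpc_m1crpc",
            "p_m1bcr_m1crpc",
            "excess_death_m0crpc",
            "excess_death_m1bcr",
            "excess_death_m1crpc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must be a probability, got {v}")
        for name, (lo, hi) in self.cis.items():
            v = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ModelError(f"CI for {name} must lie in [0, 1]: ({lo}, {hi})")
            if not lo <= v <= hi:
                raise ModelError(f"CI for {name} must bracket the estimate {v}")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities with standard deviations for PSA sampling."""

    u_m0bcr: float = 0.89
    u_m1bcr: float = 0.74
    u_m0crpc: float = 0.86
    u_m1crpc: float = 0.83
    u_death: float = 0.0
    sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "u_m0bcr": 0.14,
            "u_m1bcr": 0.27,
            "u_m0crpc": 0.17,
            "u_m1crpc": 0.13,
        }
    )

    def __post_init__(self) -> None:
        for name in ("u_m0bcr", "u_m1bcr", "u_m0crpc", "u_m1crpc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must lie in [0, 1], got {v}")
        if self.u_death != 0.0:
            raise ModelError("u_death must be 0")


@dataclass(frozen=True)
class CostSet:
    """Annual management costs in euros, with 95% CIs for PSA sampling."""

    m0bcr_first_year: float = 3524.0
    m0bcr_subsequent: float = 1844.0
    m1bcr_first_year: float = 4816.0
    m1bcr_subsequent: float = 4815.0
    m0crpc_annual: float = 5717.0
    m1crpc_annual: float = 12346.0
    cis: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "m0bcr_first_year": (2277.0, 5246.0),
            "m0bcr_subsequent": (1354.0, 2434.0),
            "m1bcr_first_year": (1615.0, 9234.0),
            "m1bcr_subsequent": (1689.0, 9308.0),
            "m0crpc_annual": (1634.0, 11869.0),
            "m1crpc_annual": (3109.0, 27740.0),
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "m0bcr_first_year",
            "m0bcr_subsequent",
            "m1bcr_first_year",
            "m1bcr_subsequent",
            "m0crpc_annual",
            "m1crpc_annual",
        ):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be non-negative")
        for name, (lo, hi) in self.cis.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ModelError(f"CI for {name} must bracket the mean {v}")


@dataclass(frozen=True)
class Strategy:
    """An imaging arm of the decision tree."""

    name: str
    se: float
    sp: float
    imaging_cost: float = 0.0
    n_positive: int = 7  # trial denominators used for binomial PSA draws
    n_negative: int = 48
    sample_accuracy: bool = True  # set False to pin se/sp in the PSA

    def __post_init__(self) -> None:
        if not (0.0 <= self.se <= 1.0 and 0.0 <= self.sp <= 1.0):
            raise ModelError(f"strategy {self.name}: se/sp must lie in [0, 1]")
        if self.imaging_cost < 0:
            raise ModelError(f"strategy {self.name}: imaging cost must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: cohort, discounting, counting and misdiagnosis policies.

    counting_method
        How state membership is credited per cycle: ``"life-table"``
        (average of start- and end-of-cycle occupancy, the default),
        ``"beginning"`` or ``"end"``.
    fp_policy
        ``"persistent-m1"`` (default) or ``"merge-m0"``; see module docs.
    fp_cost / fn_cost
        Names of :class:`CostSet` fields charged to the misdiagnosis states
        (false positives every cycle they remain misclassified; false
        negatives for their single tunnel cycle).
    fn_tunnel
        Transition row applied during the tunnel cycle: ``"m1-row"``
        (metastatic progression, the default) or ``"m0-survival"``
        (background mortality only, then correction).
    joint_progression
        Semantics of the combined m0-BCR -> m1-CRPC arm: ``"combine"``
        (rate-additive, default) or ``"product"``.
    """

    start_age: int = 70
    cohort_size: int = 10_000
    discount_rate: float = 0.04
    horizon: Optional[int] = None  # cycles; None = run to the life-table terminal age
    counting_method: str = "life-table"
    fp_policy: str = "persistent-m1"
    fp_cost: str = "m1bcr_subsequent"
    fn_cost: str = "m0bcr_first_year"
    fn_tunnel: str = "m1-row"
    joint_progression: str = "combine"
    discount_first_cycle: bool = False
    on_invalid_row: str = "error"  # or "clamp"
    half_cycle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ModelError("discount_rate must be >= 0")
        if self.cohort_size <= 0:
            raise ModelError("cohort_size must be positive")
        if self.horizon is not None and self.horizon < 1:
            raise ModelError("horizon must be >= 1 cycle")
        if self.counting_method not in ("life-table", "beginning", "end"):
            raise ModelError(f"unknown counting_method {self.counting_method!r}")
        if self.fp_policy not in ("persistent-m1", "merge-m0"):
            raise ModelError(f"unknown fp_policy {self.fp_policy!r}")
        if self.fn_tunnel not in ("m1-row", "m0-survival"):
            raise ModelError(f"unknown fn_tunnel {self.fn_tunnel!r}")
        if self.joint_progression not in ("combine", "product"):
            raise ModelError(f"unknown joint_progression {self.joint_progression!r}")
        if self.on_invalid_row not in ("error", "clamp"):
            raise ModelError(f"unknown on_invalid_row {self.on_invalid_row!r}")


# ---------------------------------------------------------------------------
# probability algebra


def prob_to_rate(p: float) -> float:
    """Annual probability -> annual rate, ``r = -ln(1 - p)``."""
    if not 0.0 <= p < 1.0:
        raise ModelError(f"probability must lie in [0, 1), got {p}")
    return -math.log1p(-p)


def rate_to_prob(r: float) -> float:
    if r < 0:
        raise ModelError(f"rate must be >= 0, got {r}")
    return -math.expm1(-r)


def combine_probs(ps: Iterable[float]) -> float:
    """Combine competing annual probabilities additively on the rate scale.

    ``p* = 1 - prod_i (1 - p_i)``; any ``p_i = 1`` yields 1.
    """
    surv = 1.0
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ModelError(f"probability must lie in [0, 1], got {p}")
        surv *= 1.0 - p
    return 1.0 - surv


# ---------------------------------------------------------------------------
# transition structure


def _finish_row(row: np.ndarray, stay: HealthState, label: str, config: ModelConfig) -> np.ndarray:
    out = row.sum()
    if out > 1.0 + _ROW_TOL:
        if config.on_invalid_row == "clamp":
            row /= out
            out = 1.0
        else:
            raise RenormalizationError(
                f"outflows from {label} sum to {out:.6f} > 1; "
                "reduce the offending parameters or set on_invalid_row='clamp'"
            )
    row[stay] += 1.0 - out
    return row


def build_transition_row(
    state: HealthState,
    params: TransitionParams,
    lt: LifeTable,
    age: float,
    config: ModelConfig = ModelConfig(),
) -> np.ndarray:
    """One row of the annual transition matrix at the given age."""
    q = lt.death_prob(age)
    row = np.zeros(N_STATES)
    S = HealthState
    if state == S.DEATH or q == 1.0:
        # absorbing state, or table closure: certain death empties the row
        row[S.DEATH] = 1.0
        return row
    if state == S.M0_BCR or (state == S.FP_MISDX and config.fp_policy == "merge-m0"):
        p01 = params.p_m0bcr_m1bcr
        p02 = params.p_m0bcr_m0crpc
        if config.joint_progression == "combine":
            p03 = combine_probs([p01, p02])
        else:
            p03 = p01 * p02
        row[S.M1_BCR] = p01
        row[S.M0_CRPC] = p02
        row[S.M1_CRPC] = p03
        row[S.DEATH] = q
        return _finish_row(row, S.M0_BCR, state.name, config)
    if state == S.M1_BCR:
        row[S.M1_CRPC] = params.p_m1bcr_m1crpc
        row[S.DEATH] = combine_probs([params.excess_death_m1bcr, q])
        return _finish_row(row, S.M1_BCR, state.name, config)
    if state == S.M0_CRPC:
        row[S.M1_CRPC] = params.p_m0crpc_m1crpc
        row[S.DEATH] = combine_probs([params.excess_death_m0crpc, q])
        return _finish_row(row, S.M0_CRPC, state.name, config)
    if state == S.M1_CRPC:
        row[S.DEATH] = combine_probs([params.excess_death_m1crpc, q])
        return _finish_row(row, S.M1_CRPC, state.name, config)
    if state == S.FN_TUNNEL:
        # one-cycle tunnel; survivors are reclassified as m1-BCR
        if config.fn_tunnel == "m1-row":
            row[S.M1_CRPC] = params.p_m1bcr_m1crpc
            row[S.DEATH] = combine_probs([params.excess_death_m1bcr, q])
        else:
            row[S.DEATH] = q
        return _finish_row(row, S.M1_BCR, state.name, config)
    if state == S.FP_MISDX:  # persistent-m1: managed as metastatic indefinitely
        row[S.M1_CRPC] = params.p_m1bcr_m1crpc
        row[S.DEATH] = combine_probs([params.excess_death_m1bcr, q])
        return _finish_row(row, S.FP_MISDX, state.name, config)
    raise ModelError(f"unhandled state {state}")


def transition_matrix(
    params: TransitionParams,
    lt: LifeTable,
    age: float,
    config: ModelConfig = ModelConfig(),
) -> np.ndarray:
    m = np.empty((N_STATES, N_STATES))
    for s in HealthState:
        m[s] = build_transition_row(s, params, lt, age, config)
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ModelError("transition rows must sum to 1")
    return m


# ---------------------------------------------------------------------------
# decision tree


def initial_allocation(prevalence: float, strategy: Strategy) -> np.ndarray:
    """Decision-tree split of unit cohort mass by diagnostic outcome."""
    if not 0.0 <= prevalence <= 1.0:
        raise ModelError(f"prevalence must lie in [0, 1], got {prevalence}")
    v = np.zeros(N_STATES)
    v[HealthState.M1_BCR] = prevalence * strategy.se
    v[HealthState.FN_TUNNEL] = prevalence * (1.0 - strategy.se)
    v[HealthState.M0_BCR] = (1.0 - prevalence) * strategy.sp
    v[HealthState.FP_MISDX] = (1.0 - prevalence) * (1.0 - strategy.sp)
    return v


# ---------------------------------------------------------------------------
# rewards


def utility_vector(utils: UtilitySet) -> np.ndarray:
    """Per-state utilities; misdiagnosed states carry the believed state's value."""
    u = np.zeros(N_STATES)
    u[HealthState.M0_BCR] = utils.u_m0bcr
    u[HealthState.M1_BCR] = utils.u_m1bcr
    u[HealthState.M0_CRPC] = utils.u_m0crpc
    u[HealthState.M1_CRPC] = utils.u_m1crpc
    u[HealthState.DEATH] = utils.u_death
    u[HealthState.FN_TUNNEL] = utils.u_m0bcr
    u[HealthState.FP_MISDX] = utils.u_m1bcr
    return u


def cost_vector(costs: CostSet, cycle: int, config: ModelConfig) -> np.ndarray:
    """Per-state annual costs for a given cycle (1-based).

    First-year totals (which include salvage radiotherapy) apply in cycle 1
    only; false negatives are billed as believed-non-metastatic patients
    for their tunnel cycle, false positives per ``config.fp_cost``.
    """
    c = np.zeros(N_STATES)
    first = cycle == 1
    c[HealthState.M0_BCR] = costs.m0bcr_first_year if first else costs.m0bcr_subsequent
    c[HealthState.M1_BCR] = costs.m1bcr_first_year if first else costs.m1bcr_subsequent
    c[HealthState.M0_CRPC] = costs.m0crpc_annual
    c[HealthState.M1_CRPC] = costs.m1crpc_annual
    c[HealthState.FN_TUNNEL] = getattr(costs, config.fn_cost)
    c[HealthState.FP_MISDX] = getattr(costs, config.fp_cost)
    return c


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy counts per cycle (row 0 = entry) and per-cycle rewards."""

    occupancy: np.ndarray  # (horizon + 1, N_STATES), in cohort counts
    discounted_costs: np.ndarray  # per cycle, per patient
    discounted_qalys: np.ndarray
    life_years: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "cycle", np.arange(len(df)))
        pad = lambda a: np.concatenate([[np.nan], a])
        df["disc_cost"] = pad(self.discounted_costs)
        df["disc_qalys"] = pad(self.discounted_qalys)
        df["life_years"] = pad(self.life_years)
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-patient outcomes for one imaging strategy."""

    name: str
    life_years: float
    life_years_undiscounted: float
    qalys: float
    cost: float

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ModelError("QALYs cannot exceed (discounted) life-years")


def _counting_weights(before: np.ndarray, after: np.ndarray, method: str) -> np.ndarray:
    if method == "life-table":
        return 0.5 * (before + after)
    if method == "beginning":
        return before
    return after


def run_markov(
    config: ModelConfig,
    params: TransitionParams,
    lt: LifeTable,
    alloc: np.ndarray,
    costs: CostSet,
    utils: UtilitySet,
    imaging_cost: float = 0.0,
    name: str = "",
) -> tuple[CohortTrace, StrategyResult]:
    """Evolve the cohort and accumulate discounted per-patient outcomes.

    Cycle ``t`` (1-based) uses the transition matrix at age
    ``start_age + t - 1`` and discounts rewards by ``(1 + d)^-(t - 1)``
    (cycle 1 undiscounted unless ``discount_first_cycle``).  The imaging
    cost is charged once at entry, undiscounted.
    """
    alloc = np.asarray(alloc, dtype=float)
    if alloc.shape != (N_STATES,) or alloc.min() < -1e-12:
        raise ModelError("allocation must be a non-negative vector over the states")
    if not math.isclose(alloc.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ModelError(f"allocation must sum to 1, got {alloc.sum()}")
    if alloc[HealthState.DEATH] > 0 and alloc[HealthState.DEATH] < 1.0:
        raise ModelError("allocation cannot place partial mass in DEATH at entry")

    horizon = config.horizon
    if horizon is None:
        horizon = max(1, lt.terminal_age - config.start_age + 1)

    uvec = utility_vector(utils)
    occupancy = np.empty((horizon + 1, N_STATES))
    occupancy[0] = alloc
    disc_costs = np.empty(horizon)
    disc_qalys = np.empty(horizon)
    cycle_lys = np.empty(horizon)

    s = alloc
    ly = ly_undisc = qalys = cost = 0.0
    for t in range(1, horizon + 1):
        m = transition_matrix(params, lt, config.start_age + t - 1, config)
        s_next = s @ m
        w = _counting_weights(s, s_next, config.counting_method)
        df = (1.0 + config.discount_rate) ** (
            -(t if config.discount_first_cycle else t - 1)
        )
        cvec = cost_vector(costs, t, config)
        lived = float(w @ _ALIVE)
        cycle_lys[t - 1] = lived
        disc_qalys[t - 1] = df * float(w @ uvec)
        disc_costs[t - 1] = df * float(w @ cvec)
        ly += df * lived
        ly_undisc += lived
        qalys += disc_qalys[t - 1]
        cost += disc_costs[t - 1]
        occupancy[t] = s_next
        s = s_next

    trace = CohortTrace(
        occupancy=occupancy * config.cohort_size,
        discounted_costs=disc_costs,
        discounted_qalys=disc_qalys,
        life_years=cycle_lys,
    )
    result = StrategyResult(
        name=name,
        life_years=ly,
        life_years_undiscounted=ly_undisc,
        qalys=qalys,
        cost=cost + imaging_cost,
    )
    return trace, result


def run_strategy_set(
    config: ModelConfig,
    params: TransitionParams,
    lt: LifeTable,
    costs: CostSet,
    utils: UtilitySet,
    prevalence: float,
    strategies: Sequence[Strategy],
) -> dict[str, StrategyResult]:
    """Decision tree + Markov run for each strategy under shared parameters."""
    if len(strategies) == 0:
        raise ModelError("need at least one strategy")
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ModelError(f"duplicate strategy names in {names}")
    out: dict[str, StrategyResult] = {}
    for strat in strategies:
        alloc = initial_allocation(prevalence, strat)
        _, res = run_markov(
            config, params, lt, alloc, costs, utils,
            imaging_cost=strat.imaging_cost, name=strat.name,
        )
        out[strat.name] = res
    return out


@dataclass(frozen=True)
class ValidationResult:
    """Undiscounted life expectancies from the no-imaging model runs."""

    overall: float  # prevalence-weighted mix of the two entry states
    m0_only: float
    m1_only: float
    unweighted_mean: float  # simple average of the two state-specific runs


def validate_life_expectancy(
    config: ModelConfig,
    params: TransitionParams,
    lt: LifeTable,
    prevalence: float,
) -> ValidationResult:
    """Life expectancy at entry with no imaging step and no discounting."""
    cfg = replace(config, discount_rate=0.0)
    utils = UtilitySet()
    costs = CostSet()
    e = {}
    for state in (HealthState.M0_BCR, HealthState.M1_BCR):
        alloc = np.zeros(N_STATES)
        alloc[state] = 1.0
        _, res = run_markov(cfg, params, lt, alloc, costs, utils)
        e[state] = res.life_years_undiscounted
    m0, m1 = e[HealthState.M0_BCR], e[HealthState.M1_BCR]
    return ValidationResult(
        overall=(1.0 - prevalence) * m0 + prevalence * m1,
        m0_only=m0,
        m1_only=m1,
        unweighted_mean=0.5 * (m0 + m1),
    )
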