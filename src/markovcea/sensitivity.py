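"""Deterministic (one-way) and probabilistic sensitivity analyses.

One-way DSA reruns the model with a single parameter (or a small bundle,
e.g. the first-year and subsequent-year costs of a state varied together)
pinned at each bound of its 95% CI or +/-1.96 SD range, recording the ICER
of a designated strategy pair.  The PSA redraws all uncertain parameters --
binomial for transition probabilities and test accuracies, moment-matched
beta for utilities, moment-matched gamma for costs -- and reruns the full
strategy set per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CostSet,
    LifeTable,
    ModelConfig,
    ModelError,
    Strategy,
    TransitionParams,
    UtilitySet,
    run_strategy_set,
)

__all__ = [
    "TornadoEntry",
    "DsaRange",
    "default_dsa_ranges",
    "one_way_dsa",
    "sample_parameters",
    "PsaResult",
    "run_psa",
]

Z95 = 3.92  # width of a symmetric 95% interval in standard errors


def _ci_sd(lo: float, hi: float) -> float:
    return (hi - lo) / Z95


@dataclass(frozen=True)
class DsaRange:
    """A named one-way perturbation: field -> (low, high) settings.

    ``settings`` maps dotted paths (``transitions.p_m0bcr_m1bcr``,
    ``costs.m1bcr_subsequent``, ``utilities.u_m0bcr``) to bound pairs; all
    fields in one range move to their low (resp. high) bounds together.
    """

    name: str
    settings: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.settings:
            raise ValueError(f"DSA range {self.name!r} has no settings")


_GROUPS = {"transitions": TransitionParams, "costs": CostSet, "utilities": UtilitySet}


def _apply_settings(
    params: TransitionParams,
    costs: CostSet,
    utils: UtilitySet,
    values: Mapping[str, float],
) -> tuple[TransitionParams, CostSet, UtilitySet]:
    bundle = {"transitions": params, "costs": costs, "utilities": utils}
    per_group: dict[str, dict[str, float]] = {}
    for path, value in values.items():
        group, _, fld = path.partition(".")
        if group not in bundle or not fld:
            raise ModelError(f"unknown parameter path {path!r}")
        if not hasattr(bundle[group], fld):
            raise ModelError(f"unknown field {fld!r} in {group!r}")
        per_group.setdefault(group, {})[fld] = value
    for group, kwargs in per_group.items():
        # widen the stored CI when a perturbed value escapes it, so the
        # dataclass invariant (CI brackets the estimate) keeps holding
        obj = bundle[group]
        if hasattr(obj, "cis"):
            cis = dict(obj.cis)
            for fld, v in kwargs.items():
                if fld in cis:
                    lo, hi = cis[fld]
                    cis[fld] = (min(lo, v), max(hi, v))
            kwargs = dict(kwargs, cis=cis)
        bundle[group] = replace(obj, **kwargs)
    return bundle["transitions"], bundle["costs"], bundle["utilities"]


def default_dsa_ranges(
    params: TransitionParams, costs: CostSet, utils: UtilitySet
) -> list[DsaRange]:
    """The default one-way set: metastasis transition probability, the four
    utilities, and the m0-/m1-BCR annual treatment costs (first-year and
    subsequent-year bounds moved jointly)."""
    ranges = [
        DsaRange(
            "p_m0bcr_m1bcr",
            {"transitions.p_m0bcr_m1bcr": params.cis["p_m0bcr_m1bcr"]},
        ),
        DsaRange(
            "m0bcr_costs",
            {
                "costs.m0bcr_first_year": costs.cis["m0bcr_first_year"],
                "costs.m0bcr_subsequent": costs.cis["m0bcr_subsequent"],
            },
        ),
        DsaRange(
            "m1bcr_costs",
            {
                "costs.m1bcr_first_year": costs.cis["m1bcr_first_year"],
                "costs.m1bcr_subsequent": costs.cis["m1bcr_subsequent"],
            },
        ),
    ]
    for name, sd in utils.sds.items():
        u = getattr(utils, name)
        lo = max(0.0, u - 1.96 * sd)
        hi = min(1.0, u + 1.96 * sd)
        ranges.append(DsaRange(name, {f"utilities.{name}": (lo, hi)}))
    return ranges


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_settings: Mapping[str, float]
    high_settings: Mapping[str, float]
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pair_icer(results: Mapping[str, object], pair: tuple[str, str]) -> float:
    ref, target = results[pair[0]], results[pair[1]]
    dq = target.qalys - ref.qalys
    if dq == 0:
        raise ModelError(f"zero QALY difference between {pair[0]} and {pair[1]}")
    return (target.cost - ref.cost) / dq


def one_way_dsa(
    config: ModelConfig,
    params: TransitionParams,
    lt: LifeTable,
    costs: CostSet,
    utils: UtilitySet,
    prevalence: float,
    strategies: Sequence[Strategy],
    ranges: Sequence[DsaRange],
    comparator_pair: tuple[str, str] = ("DW-MRI", "FCH"),
) -> list[TornadoEntry]:
    """Tornado table for the designated comparison, sorted by ICER spread.

    ``comparator_pair`` is (reference, target); the ICER is recomputed with
    each range at its low and at its high bound, everything else at base
    case.  Invalid transition rows at a bound are reported as errors naming
    the parameter and bound.
    """
    entries = []
    for rng in ranges:
        icers = {}
        for which, idx in (("low", 0), ("high", 1)):
            settings = {path: bounds[idx] for path, bounds in rng.settings.items()}
            try:
                p2, c2, u2 = _apply_settings(params, costs, utils, settings)
                results = run_strategy_set(
                    config, p2, lt, c2, u2, prevalence, strategies
                )
                icers[which] = _pair_icer(results, comparator_pair)
            except ModelError as exc:
                raise ModelError(
                    f"DSA range {rng.name!r} at its {which} bound: {exc}"
                ) from exc
        entries.append(
            TornadoEntry(
                parameter=rng.name,
                low_settings={p: b[0] for p, b in rng.settings.items()},
                high_settings={p: b[1] for p, b in rng.settings.items()},
                icer_at_low=icers["low"],
                icer_at_high=icers["high"],
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _draw_binomial_prob(rng: np.random.Generator, p: float, lo: float, hi: float) -> float:
    """k/n draw with n inferred from the CI half-width (se = width / 3.92)."""
    se = _ci_sd(lo, hi)
    if se == 0.0 or p in (0.0, 1.0):
        return p
    n_eff = max(1, round(p * (1.0 - p) / se**2))
    return rng.binomial(n_eff, p) / n_eff


def _draw_gamma(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    sd = _ci_sd(lo, hi)
    if sd == 0.0 or mean == 0.0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    if not np.isfinite(shape) or not np.isfinite(scale):
        raise ModelError(f"non-finite gamma moments for mean {mean}, sd {sd}")
    return float(rng.gamma(shape, scale))


def _draw_beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    var = min(sd**2, mean * (1.0 - mean) * 0.999)  # beta feasibility bound
    if var <= 0.0:
        return mean
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def sample_parameters(
    params: TransitionParams,
    costs: CostSet,
    utils: UtilitySet,
    strategies: Sequence[Strategy],
    rng: np.random.Generator,
) -> tuple[TransitionParams, CostSet, UtilitySet, list[Strategy]]:
    """One Monte Carlo perturbation of every uncertain parameter.

    Transition probabilities are drawn as ``k/n`` with ``n`` matched to the
    CI width; costs from gamma distributions moment-matched to the mean and
    ``(hi - lo)/3.92``; utilities from moment-matched beta distributions;
    strategy accuracies binomially with their trial denominators.  Zero
    variances reproduce the base case exactly.
    """
    t_draws = {
        name: _draw_binomial_prob(rng, getattr(params, name), lo, hi)
        for name, (lo, hi) in params.cis.items()
    }
    new_cis = {
        name: (min(params.cis[name][0], v), max(params.cis[name][1], v))
        for name, v in t_draws.items()
    }
    params2 = replace(params, cis=new_cis, **t_draws)

    c_draws = {
        name: _draw_gamma(rng, getattr(costs, name), lo, hi)
        for name, (lo, hi) in costs.cis.items()
    }
    c_cis = {
        name: (min(costs.cis[name][0], v), max(costs.cis[name][1], v))
        for name, v in c_draws.items()
    }
    costs2 = replace(costs, cis=c_cis, **c_draws)

    u_draws = {
        name: _draw_beta(rng, getattr(utils, name), sd)
        for name, sd in utils.sds.items()
    }
    utils2 = replace(utils, **u_draws)

    strategies2 = [
        replace(
            s,
            se=rng.binomial(s.n_positive, s.se) / s.n_positive,
            sp=rng.binomial(s.n_negative, s.sp) / s.n_negative,
        )
        if s.sample_accuracy
        else s
        for s in strategies
    ]
    return params2, costs2, utils2, strategies2


@dataclass(frozen=True)
class PsaResult:
    """Per-draw results plus incremental summaries for one strategy pair.

    ``mean_icer`` is the ratio of mean incremental cost to mean incremental
    QALYs (the sign-stable headline statistic); ``icer_per_draw`` keeps the
    per-iteration ratios for completeness.
    """

    draws: pd.DataFrame  # columns: iteration, strategy, cost, qalys
    pair: tuple[str, str]
    mean_incremental_cost: float
    mean_incremental_qalys: float
    mean_icer: float
    icer_per_draw: np.ndarray
    seed: int

    def samples(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-strategy (costs, qalys) arrays, draw-aligned, for CEAC input."""
        out = {}
        for name, grp in self.draws.groupby("strategy", sort=False):
            g = grp.sort_values("iteration")
            out[name] = (g["cost"].to_numpy(), g["qalys"].to_numpy())
        return out


def run_psa(
    config: ModelConfig,
    params: TransitionParams,
    lt: LifeTable,
    costs: CostSet,
    utils: UtilitySet,
    prevalence: float,
    strategies: Sequence[Strategy],
    n_iter: int = 1000,
    seed: int = 0,
    pair: tuple[str, str] = ("DW-MRI", "FCH"),
) -> PsaResult:
    """Monte Carlo PSA: ``n_iter`` redraws of all parameters, full rerun each.

    Fully reproducible for a given seed.  Incremental statistics are taken
    between ``pair = (reference, target)``.
    """
    if n_iter < 1:
        raise ModelError("n_iter must be >= 1")
    for name in pair:
        if name not in {s.name for s in strategies}:
            raise ModelError(f"pair strategy {name!r} not among strategies")
    rng = np.random.default_rng(seed)
    records = []
    inc_cost = np.empty(n_iter)
    inc_qaly = np.empty(n_iter)
    for it in range(n_iter):
        p2, c2, u2, s2 = sample_parameters(params, costs, utils, strategies, rng)
        results = run_strategy_set(config, p2, lt, c2, u2, prevalence, s2)
        for nm, res in results.items():
            records.append((it, nm, res.cost, res.qalys))
        inc_cost[it] = results[pair[1]].cost - results[pair[0]].cost
        inc_qaly[it] = results[pair[1]].qalys - results[pair[0]].qalys
    draws = pd.DataFrame(records, columns=["iteration", "strategy", "cost", "qalys"])
    with np.errstate(divide="ignore", invalid="ignore"):
        per_draw = inc_cost / inc_qaly
    return PsaResult(
        draws=draws,
        pair=pair,
        mean_incremental_cost=float(inc_cost.mean()),
        mean_incremental_qalys=float(inc_qaly.mean()),
        mean_icer=float(inc_cost.mean() / inc_qaly.mean()),
        icer_per_draw=per_draw,
        seed=seed,
    )
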