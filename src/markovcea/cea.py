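"""Cost-effectiveness outputs: ICERs, the efficiency frontier, net monetary
benefit and acceptability curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import StrategyResult

__all__ = [
    "UndefinedICER",
    "icer",
    "FrontierEntry",
    "efficiency_frontier",
    "nmb",
    "ceac",
]

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


class UndefinedICER(ValueError):
    """Signalled when the QALY difference between two strategies is zero."""


def icer(a: StrategyResult, b: StrategyResult) -> float:
    """Incremental cost-effectiveness ratio of ``b`` against ``a``.

    ``(cost_b - cost_a) / (qalys_b - qalys_a)``, in currency per QALY.
    A negative value indicates a dominance situation (one strategy is both
    cheaper and more effective); interpretation is left to the caller.
    """
    dq = b.qalys - a.qalys
    if dq == 0.0:
        raise UndefinedICER(
            f"strategies {a.name!r} and {b.name!r} have equal QALYs"
        )
    return (b.cost - a.cost) / dq


@dataclass(frozen=True)
class FrontierEntry:
    name: str
    status: str
    cost: float
    qalys: float
    icer_vs_previous: Optional[float] = None


def efficiency_frontier(results: Sequence[StrategyResult]) -> list[FrontierEntry]:
    """Classify strategies by strict and extended dominance.

    Strategies are sorted by ascending QALYs (cost breaking ties).  A
    strategy is strictly dominated when some other strategy costs no more
    and yields no fewer QALYs, with at least one strict inequality.  The
    survivors are then swept for extended dominance: a member is removed
    while its ICER against the previous frontier member exceeds that of the
    next member against the same comparator, so frontier ICERs end up
    strictly increasing.  Equal-QALY, equal-cost strategies both stay on
    the frontier with no ICER defined between them.
    """
    if len(results) < 2:
        return [
            FrontierEntry(r.name, ON_FRONTIER, r.cost, r.qalys) for r in results
        ]
    ordered = sorted(results, key=lambda r: (r.qalys, r.cost, r.name))

    status: dict[str, str] = {}
    for r in ordered:
        dominated = any(
            o.cost <= r.cost
            and o.qalys >= r.qalys
            and (o.cost < r.cost or o.qalys > r.qalys)
            for o in ordered
            if o is not r
        )
        status[r.name] = DOMINATED if dominated else ON_FRONTIER

    candidates = [r for r in ordered if status[r.name] == ON_FRONTIER]
    # iterative extended-dominance sweep until successive ICERs increase
    while True:
        removed = False
        for i in range(1, len(candidates) - 1):
            prev, mid, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            try:
                if icer(prev, mid) >= icer(prev, nxt):
                    status[mid.name] = EXTENDED_DOMINATED
                    del candidates[i]
                    removed = True
                    break
            except UndefinedICER:
                continue
        if not removed:
            break

    entries: list[FrontierEntry] = []
    prev_on = None
    for r in ordered:
        st = status[r.name]
        ratio = None
        if st == ON_FRONTIER and prev_on is not None:
            try:
                ratio = icer(prev_on, r)
            except UndefinedICER:
                ratio = None
        if st == ON_FRONTIER:
            prev_on = r
        entries.append(FrontierEntry(r.name, st, r.cost, r.qalys, ratio))
    return entries


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` per QALY."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * result.qalys - result.cost


def ceac(
    psa_samples: Mapping[str, tuple[np.ndarray, np.ndarray]],
    wtp_grid: Sequence[float],
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    ``psa_samples`` maps strategy name to ``(costs, qalys)`` arrays of
    per-draw results; all strategies must share the draw count.  For each
    threshold the returned frame holds the fraction of draws in which each
    strategy attains the highest net monetary benefit, ties split equally,
    so rows sum to 1.
    """
    if not psa_samples:
        raise ValueError("psa_samples is empty")
    names = list(psa_samples)
    costs = np.column_stack([np.asarray(psa_samples[n][0], float) for n in names])
    qalys = np.column_stack([np.asarray(psa_samples[n][1], float) for n in names])
    if costs.shape != qalys.shape or costs.shape[0] == 0:
        raise ValueError("per-strategy cost/qaly arrays must align and be non-empty")
    n_draws = costs.shape[0]
    rows = []
    for lam in wtp_grid:
        benefit = lam * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        winners = np.isclose(benefit, best)
        share = winners / winners.sum(axis=1, keepdims=True)
        rows.append(share.mean(axis=0))
    out = pd.DataFrame(rows, columns=names)
    out.insert(0, "wtp", np.asarray(wtp_grid, float))
    out.attrs["n_draws"] = n_draws
    return out
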