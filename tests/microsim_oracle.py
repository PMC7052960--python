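"""Independent per-patient Monte Carlo oracle for the cohort engine.

Rebuilds the annual transition rows from the parameter values with its own
arithmetic and advances sampled cohorts with multinomial draws; shares no
code path with the matrix engine it cross-checks.
"""

import numpy as np

from markovcea.model import initial_allocation


def oracle_rows(params, lt, age):
    q = lt.death_prob(age)
    if q == 1.0:
        rows = np.zeros((7, 7))
        rows[:, 4] = 1.0
        return rows

    def anyof(*ps):
        out = 1.0
        for p in ps:
            out *= 1 - p
        return 1 - out

    p01, p02 = params.p_m0bcr_m1bcr, params.p_m0bcr_m0crpc
    p03 = anyof(p01, p02)
    rows = np.zeros((7, 7))
    rows[0, [1, 2, 3, 4]] = [p01, p02, p03, q]
    rows[0, 0] = 1 - rows[0].sum()
    d1 = anyof(params.excess_death_m1bcr, q)
    rows[1, [3, 4]] = [params.p_m1bcr_m1crpc, d1]
    rows[1, 1] = 1 - rows[1].sum()
    rows[2, [3, 4]] = [params.p_m0crpc_m1crpc, anyof(params.excess_death_m0crpc, q)]
    rows[2, 2] = 1 - rows[2].sum()
    rows[3, 4] = anyof(params.excess_death_m1crpc, q)
    rows[3, 3] = 1 - rows[3].sum()
    rows[4, 4] = 1.0
    rows[5, [3, 4]] = [params.p_m1bcr_m1crpc, d1]
    rows[5, 1] = 1 - rows[5].sum()  # tunnel survivors re-labelled m1-BCR
    rows[6, [3, 4]] = [params.p_m1bcr_m1crpc, d1]
    rows[6, 6] = 1 - rows[6].sum()  # persistent misclassification
    return rows


def simulate_batch(bundle, strat, n_patients, rng):
    """Mean per-patient discounted (QALYs, cost) from one sampled cohort."""
    cfg = bundle.model_config
    params, costs, utils = bundle.transitions, bundle.costs, bundle.utilities
    lt = bundle.life_table
    alloc = initial_allocation(bundle.prevalence, strat)
    counts = rng.multinomial(n_patients, alloc)
    qaly = cost = 0.0
    uvec = np.array([utils.u_m0bcr, utils.u_m1bcr, utils.u_m0crpc,
                     utils.u_m1crpc, 0.0, utils.u_m0bcr, utils.u_m1bcr])
    horizon = lt.terminal_age - cfg.start_age + 1
    for t in range(1, horizon + 1):
        rows = oracle_rows(params, lt, cfg.start_age + t - 1)
        nxt = np.zeros(7, dtype=np.int64)
        for s_idx in range(7):
            if counts[s_idx]:
                nxt += rng.multinomial(counts[s_idx], rows[s_idx])
        w = 0.5 * (counts + nxt)  # life-table counting
        cvec = np.array([
            costs.m0bcr_first_year if t == 1 else costs.m0bcr_subsequent,
            costs.m1bcr_first_year if t == 1 else costs.m1bcr_subsequent,
            costs.m0crpc_annual, costs.m1crpc_annual, 0.0,
            getattr(costs, cfg.fn_cost), getattr(costs, cfg.fp_cost),
        ])
        df = (1 + cfg.discount_rate) ** -(t - 1)
        qaly += df * float(w @ uvec)
        cost += df * float(w @ cvec)
        counts = nxt
    return qaly / n_patients, cost / n_patients + strat.imaging_cost
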