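import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea.model import (
    CostSet,
    HealthState,
    ModelConfig,
    ModelError,
    RenormalizationError,
    Strategy,
    TransitionParams,
    UtilitySet,
    build_transition_row,
    combine_probs,
    initial_allocation,
    prob_to_rate,
    rate_to_prob,
    run_markov,
    run_strategy_set,
    transition_matrix,
    validate_life_expectancy,
)

S = HealthState

ZERO_COSTS = CostSet(
    m0bcr_first_year=0, m0bcr_subsequent=0, m1bcr_first_year=0,
    m1bcr_subsequent=0, m0crpc_annual=0, m1crpc_annual=0, cis={},
)
UNIT_UTILS = UtilitySet(u_m0bcr=1, u_m1bcr=1, u_m0crpc=1, u_m1crpc=1, sds={})
NO_DISEASE = TransitionParams(
    p_m0bcr_m1bcr=0, p_m0bcr_m0crpc=0, p_m0crpc_m1crpc=0, p_m1bcr_m1crpc=0,
    excess_death_m0crpc=0, excess_death_m1bcr=0, excess_death_m1crpc=0, cis={},
)


def unit_alloc(state):
    v = np.zeros(len(S))
    v[state] = 1.0
    return v


class TestProbabilityAlgebra:
    def test_prob_to_rate_zero(self):
        assert prob_to_rate(0.0) == 0.0

    def test_prob_to_rate_inverse_pair(self):
        assert prob_to_rate(1 - math.exp(-1)) == pytest.approx(1.0)
        assert rate_to_prob(prob_to_rate(0.37)) == pytest.approx(0.37)

    def test_prob_to_rate_closed_form(self):
        assert prob_to_rate(0.0288) == pytest.approx(-math.log(1 - 0.0288))
        assert prob_to_rate(0.0288) == pytest.approx(0.0292229, abs=1e-6)

    def test_prob_one_rejected(self):
        with pytest.raises(ModelError):
            prob_to_rate(1.0)

    def test_combine_independent_event_oracle(self):
        assert combine_probs([0.0288, 0.0279]) == pytest.approx(1 - 0.9712 * 0.9721)
        assert combine_probs([0.2933, 0.05]) == pytest.approx(1 - 0.7067 * 0.95)

    def test_combine_identity_element(self):
        assert combine_probs([0.42, 0.0]) == pytest.approx(0.42)

    def test_combine_certain_event(self):
        assert combine_probs([0.3, 1.0]) == 1.0

    @given(ps=st.lists(st.floats(0, 0.99), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_combine_equals_rate_addition(self, ps):
        via_rates = rate_to_prob(sum(prob_to_rate(p) for p in ps))
        assert combine_probs(ps) == pytest.approx(via_rates)


class TestTransitionRows:
    def test_death_absorbing(self, lt):
        row = build_transition_row(S.DEATH, TransitionParams(), lt, 70)
        expected = np.zeros(len(S))
        expected[S.DEATH] = 1.0
        np.testing.assert_array_equal(row, expected)

    def test_m1crpc_row_at_zero_mortality(self, const_q_table):
        row = build_transition_row(S.M1_CRPC, TransitionParams(), const_q_table(0.0), 70)
        assert row[S.DEATH] == pytest.approx(0.2933)
        assert row[S.M1_CRPC] == pytest.approx(0.7067)

    def test_m0bcr_row_arithmetic(self, const_q_table):
        row = build_transition_row(S.M0_BCR, TransitionParams(), const_q_table(0.02), 70)
        assert row[S.DEATH] == pytest.approx(0.02)
        assert row[S.M1_BCR] == pytest.approx(0.0288)
        assert row[S.M0_CRPC] == pytest.approx(0.0279)
        assert row[S.M1_CRPC] == pytest.approx(0.055896, abs=5e-7)
        assert row[S.M0_BCR] == pytest.approx(0.867404, abs=5e-7)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("age", [70, 85, 100, 109, 110, 140])
    def test_rows_sum_to_one_all_states(self, lt, age):
        m = transition_matrix(TransitionParams(), lt, age)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_no_backward_transitions(self, lt):
        m = transition_matrix(TransitionParams(), lt, 75)
        assert m[S.M0_CRPC, S.M0_BCR] == 0.0
        assert m[S.M0_CRPC, S.M1_BCR] == 0.0
        assert m[S.M1_CRPC, S.M1_BCR] == 0.0
        assert m[S.M1_BCR, S.M0_BCR] == 0.0

    def test_tunnel_states_empty_in_one_cycle(self, lt):
        m = transition_matrix(TransitionParams(), lt, 75)
        assert m[S.FN_TUNNEL, S.FN_TUNNEL] == 0.0
        cfg = ModelConfig(fp_policy="merge-m0")
        m2 = transition_matrix(TransitionParams(), lt, 75, cfg)
        assert m2[S.FP_MISDX, S.FP_MISDX] == 0.0

    def test_overflowing_row_raises_with_row_name(self, const_q_table):
        params = replace(TransitionParams(), p_m0crpc_m1crpc=0.97, cis={})
        with pytest.raises(RenormalizationError, match="M0_CRPC"):
            build_transition_row(S.M0_CRPC, params, const_q_table(0.2), 70)

    def test_overflowing_row_clamp_mode(self, const_q_table):
        params = replace(TransitionParams(), p_m0crpc_m1crpc=0.97, cis={})
        cfg = ModelConfig(on_invalid_row="clamp")
        row = build_transition_row(S.M0_CRPC, params, const_q_table(0.2), 70, cfg)
        assert row.sum() == pytest.approx(1.0)
        assert row.min() >= 0.0


class TestInitialAllocation:
    def test_trial_counts_example(self):
        strat = Strategy("NaF", se=5 / 7, sp=44 / 48)
        v = initial_allocation(7 / 55, strat)
        assert v[S.M0_BCR] == pytest.approx(0.8)
        assert v[S.FP_MISDX] == pytest.approx(4 / 55)
        assert v[S.M1_BCR] == pytest.approx(5 / 55)
        assert v[S.FN_TUNNEL] == pytest.approx(2 / 55)
        assert v.sum() == pytest.approx(1.0)

    def test_perfect_test(self):
        v = initial_allocation(0.3, Strategy("X", se=1.0, sp=1.0))
        assert v[S.FP_MISDX] == 0.0
        assert v[S.FN_TUNNEL] == 0.0

    def test_zero_prevalence_perfect_specificity(self):
        v = initial_allocation(0.0, Strategy("X", se=0.5, sp=1.0))
        assert v[S.M0_BCR] == 1.0

    @given(
        prev=st.floats(0, 1),
        se=st.floats(0, 1),
        sp=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_masses_sum_to_one(self, prev, se, sp):
        v = initial_allocation(prev, Strategy("X", se=se, sp=sp))
        assert v.sum() == pytest.approx(1.0)


class TestRunMarkov:
    def test_all_mass_in_death(self, lt):
        _, res = run_markov(
            ModelConfig(), TransitionParams(), lt, unit_alloc(S.DEATH),
            CostSet(), UtilitySet(), imaging_cost=302.0,
        )
        assert res.life_years == 0.0
        assert res.qalys == 0.0
        assert res.cost == 302.0

    def test_partial_death_mass_rejected(self, lt):
        v = np.zeros(len(S))
        v[S.DEATH] = 0.5
        v[S.M0_BCR] = 0.5
        with pytest.raises(ModelError):
            run_markov(ModelConfig(), TransitionParams(), lt, v, CostSet(), UtilitySet())

    def test_pure_survival_reduction_end_counting(self, lt):
        # with disease switched off, end-of-cycle counting accumulates
        # exactly sum_k S(k), the half-cycle-off life expectancy
        cfg = ModelConfig(discount_rate=0.0, counting_method="end")
        _, res = run_markov(cfg, NO_DISEASE, lt, unit_alloc(S.M0_BCR), ZERO_COSTS, UNIT_UTILS)
        assert res.qalys == pytest.approx(lt.life_expectancy(70, half_cycle=False), abs=1e-9)
        assert res.life_years == pytest.approx(res.qalys, abs=1e-12)

    def test_pure_survival_reduction_life_table_counting(self, lt):
        # life-table counting adds exactly the half-cycle continuity term
        cfg = ModelConfig(discount_rate=0.0, counting_method="life-table")
        _, res = run_markov(cfg, NO_DISEASE, lt, unit_alloc(S.M0_BCR), ZERO_COSTS, UNIT_UTILS)
        assert res.life_years == pytest.approx(lt.life_expectancy(70, half_cycle=True), abs=1e-9)

    def test_conservation_and_monotone_death(self, bundle):
        strat = bundle.strategy_set("onsite")[0]
        alloc = initial_allocation(bundle.prevalence, strat)
        trace, _ = run_markov(
            bundle.model_config, bundle.transitions, bundle.life_table,
            alloc, bundle.costs, bundle.utilities,
        )
        sums = trace.occupancy.sum(axis=1)
        np.testing.assert_allclose(sums, bundle.model_config.cohort_size, rtol=1e-9)
        deaths = trace.occupancy[:, S.DEATH]
        assert np.all(np.diff(deaths) >= -1e-9)
        assert deaths[-1] == pytest.approx(bundle.model_config.cohort_size, rel=1e-9)

    def test_discounted_below_undiscounted(self, bundle):
        alloc = initial_allocation(bundle.prevalence, bundle.strategy_set("onsite")[0])
        _, res = run_markov(
            bundle.model_config, bundle.transitions, bundle.life_table,
            alloc, bundle.costs, bundle.utilities,
        )
        assert res.life_years < res.life_years_undiscounted
        cfg0 = replace(bundle.model_config, discount_rate=0.0)
        _, res0 = run_markov(
            cfg0, bundle.transitions, bundle.life_table, alloc,
            bundle.costs, bundle.utilities,
        )
        assert res0.life_years == pytest.approx(res0.life_years_undiscounted, abs=1e-12)

    def test_qalys_bounded_by_life_years(self, bundle):
        alloc = initial_allocation(bundle.prevalence, bundle.strategy_set("onsite")[1])
        _, res = run_markov(
            bundle.model_config, bundle.transitions, bundle.life_table,
            alloc, bundle.costs, bundle.utilities,
        )
        assert 0.0 < res.qalys <= res.life_years

    def test_qalys_monotone_in_specificity(self, bundle):
        # fewer false positives -> strictly more QALYs (they avoid the
        # persistent metastatic-management pathway)
        qalys = []
        for sp in (0.7, 0.85, 1.0):
            res = run_strategy_set(
                bundle.model_config, bundle.transitions, bundle.life_table,
                bundle.costs, bundle.utilities, bundle.prevalence,
                [Strategy("X", se=0.7, sp=sp)],
            )["X"]
            qalys.append(res.qalys)
        assert qalys[0] < qalys[1] < qalys[2]

    def test_sensitivity_only_relabels_first_cycle(self, bundle):
        # true positives and corrected false negatives follow the same
        # transition row, so se only shifts first-cycle rewards: QALYs move
        # by less than one cycle's utility gap times the re-labelled mass
        res = {}
        for se in (0.2, 0.8):
            res[se] = run_strategy_set(
                bundle.model_config, bundle.transitions, bundle.life_table,
                bundle.costs, bundle.utilities, bundle.prevalence,
                [Strategy("X", se=se, sp=0.9)],
            )["X"]
        moved_mass = bundle.prevalence * 0.6
        gap = bundle.utilities.u_m0bcr - bundle.utilities.u_m1bcr
        assert abs(res[0.8].qalys - res[0.2].qalys) <= moved_mass * gap + 1e-9

    def test_cost_monotone_in_state_cost(self, bundle):
        costs_hi = replace(bundle.costs, m1crpc_annual=20_000.0, cis={})
        base, hi = (
            run_strategy_set(
                bundle.model_config, bundle.transitions, bundle.life_table,
                c, bundle.utilities, bundle.prevalence,
                [Strategy("X", se=0.7, sp=0.9)],
            )["X"].cost
            for c in (bundle.costs, costs_hi)
        )
        assert hi > base

    def test_trace_frame_layout(self, bundle):
        alloc = initial_allocation(bundle.prevalence, bundle.strategy_set("onsite")[0])
        trace, _ = run_markov(
            bundle.model_config, bundle.transitions, bundle.life_table,
            alloc, bundle.costs, bundle.utilities,
        )
        df = trace.to_frame()
        assert list(df.columns[:1]) == ["cycle"]
        assert set(s.name for s in S) <= set(df.columns)
        assert len(df) == trace.occupancy.shape[0]


class TestRunStrategySet:
    def test_cost_separability(self, bundle):
        res = run_strategy_set(
            bundle.model_config, bundle.transitions, bundle.life_table,
            bundle.costs, bundle.utilities, bundle.prevalence,
            [
                Strategy("cheap", se=0.7, sp=0.9, imaging_cost=100.0),
                Strategy("dear", se=0.7, sp=0.9, imaging_cost=900.0),
            ],
        )
        assert res["dear"].cost - res["cheap"].cost == pytest.approx(800.0)
        assert res["dear"].qalys == pytest.approx(res["cheap"].qalys)

    def test_duplicate_names_rejected(self, bundle):
        with pytest.raises(ModelError, match="duplicate"):
            run_strategy_set(
                bundle.model_config, bundle.transitions, bundle.life_table,
                bundle.costs, bundle.utilities, bundle.prevalence,
                [Strategy("X", se=0.5, sp=0.5), Strategy("X", se=0.6, sp=0.6)],
            )

    def test_empty_strategy_list_rejected(self, bundle):
        with pytest.raises(ModelError):
            run_strategy_set(
                bundle.model_config, bundle.transitions, bundle.life_table,
                bundle.costs, bundle.utilities, bundle.prevalence, [],
            )


class TestValidation:
    def test_no_disease_reduces_to_life_table(self, lt):
        v = validate_life_expectancy(ModelConfig(), NO_DISEASE, lt, 7 / 55)
        e = lt.life_expectancy(70, half_cycle=True)
        assert v.m0_only == pytest.approx(e, abs=1e-9)
        assert v.m1_only == pytest.approx(e, abs=1e-9)
        assert v.overall == pytest.approx(e, abs=1e-9)

    def test_mixture_bound(self, bundle):
        v = validate_life_expectancy(
            bundle.model_config, bundle.transitions, bundle.life_table, bundle.prevalence
        )
        assert v.m1_only <= v.overall <= v.m0_only
        assert v.m1_only <= v.unweighted_mean <= v.m0_only

    def test_prevalence_weighting(self, bundle):
        v = validate_life_expectancy(
            bundle.model_config, bundle.transitions, bundle.life_table, bundle.prevalence
        )
        expected = (1 - bundle.prevalence) * v.m0_only + bundle.prevalence * v.m1_only
        assert v.overall == pytest.approx(expected)


class TestMicrosimulationOracle:
    """Cross-check against the independent per-patient simulation oracle."""

    def test_engine_matches_microsimulation(self, bundle):
        from microsim_oracle import simulate_batch

        strat = next(s for s in bundle.strategy_set("onsite") if s.name == "FCH")
        alloc = initial_allocation(bundle.prevalence, strat)
        _, res = run_markov(
            bundle.model_config, bundle.transitions, bundle.life_table,
            alloc, bundle.costs, bundle.utilities,
            imaging_cost=strat.imaging_cost,
        )
        rng = np.random.default_rng(2024)
        n_batches, batch_size = 20, 10_000  # 200k patients total
        qalys = np.empty(n_batches)
        cost = np.empty(n_batches)
        for i in range(n_batches):
            qalys[i], cost[i] = simulate_batch(bundle, strat, batch_size, rng)
        se_q = qalys.std(ddof=1) / math.sqrt(n_batches)
        se_c = cost.std(ddof=1) / math.sqrt(n_batches)
        assert res.qalys == pytest.approx(qalys.mean(), abs=3 * se_q)
        assert res.cost == pytest.approx(cost.mean(), abs=3 * se_c)
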