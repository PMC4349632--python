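"""Task engine: contingency rules, trial structure, budget enforcement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gobudget import task
from gobudget.task import (
    OfferRecord,
    TrialConfig,
    TrialLog,
    TrialState,
    draw_trial_config,
    offer_probs,
    sample_offer,
    simulate_trial,
    trial_payout,
    update_m,
)


class TestOfferProbs:
    @pytest.mark.parametrize(
        "m, expected",
        [
            (0, (1 / 3, 1 / 3, 1 / 3)),
            (1, (0.5, 0.25, 0.25)),
            (2, (0.9, 0.05, 0.05)),
        ],
    )
    def test_distributions(self, m, expected):
        probs = offer_probs(m)
        assert probs == pytest.approx(expected, abs=1e-15)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("m", [-1, 3, "x"])
    def test_invalid_contingency(self, m):
        with pytest.raises(ValueError):
            offer_probs(m)


class TestUpdateM:
    @pytest.mark.parametrize(
        "m, action, value, index, rejected, expected",
        [
            # penalty shifts for early accepted 7s and 5s
            (0, "go", 7, 3, 0, 2),
            (0, "go", 5, 2, 0, 1),
            # first offer never shifts
            (0, "go", 7, 1, 0, 0),
            # the 3-rejection lock
            (0, "go", 7, 5, 3, 0),
            (0, "go", 5, 6, 4, 0),
            # rejections and 3-token offers never shift
            (0, "nogo", 7, 2, 0, 0),
            (1, "go", 3, 4, 1, 1),
            # literal most-recent-choice rule: a later 5 relaxes m=2
            (2, "go", 5, 4, 1, 1),
        ],
    )
    def test_update_rules(self, m, action, value, index, rejected, expected):
        assert update_m(m, action, value, index, rejected) == expected

    def test_monotone_flag_forbids_improvement(self):
        assert update_m(2, "go", 5, 4, 1, m_monotone=True) == 2
        assert update_m(0, "go", 5, 4, 1, m_monotone=True) == 1

    @given(
        m=st.sampled_from([0, 1, 2]),
        value=st.sampled_from([3, 5, 7]),
        index=st.integers(2, 9),
        rejected=st.integers(3, 8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_lock_is_permanent(self, m, value, index, rejected):
        """Once three offers are rejected, no accept can change m."""
        assert update_m(m, "go", value, index, rejected) == m


class TestTrialConfig:
    def test_draw_ranges_and_determinism(self):
        rng = np.random.default_rng(0)
        cfgs = [draw_trial_config(rng) for _ in range(200)]
        assert all(7 <= c.n_offers <= 9 and 4 <= c.budget <= 6 for c in cfgs)
        rng2 = np.random.default_rng(0)
        assert cfgs == [draw_trial_config(rng2) for _ in range(200)]

    def test_draws_uniform_and_independent(self):
        """All 9 (n_offers, budget) combos near frequency 1/9."""
        rng = np.random.default_rng(123)
        n = 90_000
        counts = {}
        for _ in range(n):
            c = draw_trial_config(rng)
            counts[(c.n_offers, c.budget)] = counts.get((c.n_offers, c.budget), 0) + 1
        assert len(counts) == 9
        p = 1 / 9
        se = np.sqrt(p * (1 - p) / n)
        for combo, k in counts.items():
            assert abs(k / n - p) < 3 * se, combo

    @pytest.mark.parametrize("n_offers, budget", [(6, 5), (10, 4), (8, 3), (8, 7)])
    def test_invalid_config_rejected(self, n_offers, budget):
        with pytest.raises(ValueError):
            TrialConfig(n_offers, budget)


class TestSampleOffer:
    def test_penalty_distribution_frequencies(self):
        rng = np.random.default_rng(5)
        n = 10_000
        draws = np.array([sample_offer(2, rng) for _ in range(n)])
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(np.mean(draws == 3) - 0.9) < 3 * se

    def test_uniform_covers_support_and_reproduces(self):
        rng = np.random.default_rng(2)
        draws = [sample_offer(0, rng) for _ in range(10_000)]
        assert set(draws) == {3, 5, 7}
        rng2 = np.random.default_rng(2)
        assert draws == [sample_offer(0, rng2) for _ in range(10_000)]


def _go_policy(state, value):
    return "go"


def _nogo_policy(state, value):
    return "nogo"


class TestTrialDynamics:
    def test_forced_nogo_after_budget_exhaustion(self):
        state = TrialState(TrialConfig(8, 4))
        state.n_accepted = 4
        state.offer_index = 5
        state.current_offer_value = 7
        rec = state.step("go")
        assert rec.action == "nogo" and rec.forced

    def test_first_offer_accept_leaves_m_unchanged(self):
        state = TrialState(TrialConfig(8, 4))
        state.current_offer_value = 7
        state.step("go")
        assert state.m == 0 and state.n_accepted == 1

    def test_second_offer_accept_of_7_sets_penalty(self):
        rng = np.random.default_rng(0)
        log = simulate_trial(TrialConfig(8, 4), _go_policy, rng)
        first_7 = next(
            (r for r in log.records if r.offer_value == 7 and r.offer_index >= 2),
            None,
        )
        if first_7 is not None and first_7.offer_index < 5:
            later = [r for r in log.records if r.offer_index == first_7.offer_index + 1]
            assert later[0].m_at_offer == 2

    def test_cannot_step_past_final_offer(self):
        state = TrialState(TrialConfig(7, 4))
        state.offer_index = 8
        with pytest.raises(RuntimeError):
            state.current_offer_value = 3
            state.step("nogo")

    def test_all_nogo_trial_pays_nothing(self):
        rng = np.random.default_rng(1)
        log = simulate_trial(TrialConfig(9, 6), _nogo_policy, rng)
        assert trial_payout(log) == 0
        assert len(log.records) == 9

    def test_payout_arithmetic(self):
        cfg = TrialConfig(7, 4)
        values = [7, 5, 3, 3, 3, 3, 3]
        actions = ["go", "go", "go", "nogo", "nogo", "nogo", "nogo"]
        records, m, n_rej = [], 0, 0
        for i, (v, a) in enumerate(zip(values, actions), start=1):
            records.append(OfferRecord(i, v, m, a, False))
            m = update_m(m, a, v, i, n_rej)
            n_rej += a == "nogo"
        assert trial_payout(TrialLog(cfg, records)) == 15

    def test_over_budget_log_rejected(self):
        cfg = TrialConfig(7, 4)
        records = [OfferRecord(i, 3, 0, "go", False) for i in range(1, 8)]
        log = TrialLog(cfg, records)
        with pytest.raises(ValueError):
            trial_payout(log)
        with pytest.raises(ValueError):
            log.validate()

    @given(seed=st.integers(0, 10_000), p_go=st.floats(0.1, 0.9))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_simulated_trials_satisfy_invariants(self, seed, p_go):
        """Random-policy trials: accepts <= budget, forced flags a suffix,
        log validates."""
        rng = np.random.default_rng(seed)

        def policy(state, value):
            return "go" if rng.random() < p_go else "nogo"

        cfg = draw_trial_config(rng)
        log = simulate_trial(cfg, policy, rng)
        log.validate()
        n_go = sum(r.action == "go" for r in log.records)
        assert n_go <= cfg.budget
        forced = [r.forced for r in log.records]
        assert forced == sorted(forced)  # False..False True..True

    def test_offer_frequencies_track_frozen_contingency(self):
        """With all offers rejected, m stays 0 and values are uniform."""
        rng = np.random.default_rng(9)
        values = []
        for _ in range(2000):
            log = simulate_trial(TrialConfig(9, 6), _nogo_policy, rng)
            assert all(r.m_at_offer == 0 for r in log.records)
            values.extend(r.offer_value for r in log.records)
        freqs = np.array([values.count(v) / len(values) for v in (3, 5, 7)])
        se = np.sqrt((1 / 3) * (2 / 3) / len(values))
        assert np.all(np.abs(freqs - 1 / 3) < 4 * se)
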