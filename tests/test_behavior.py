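"""Acceptance grids, decorrelated-offer subset, robust logistic regression."""

import numpy as np
import pandas as pd
import pytest

from gobudget.behavior import (
    GroupTest,
    SeparationError,
    acceptance_grid,
    group_ttest,
    logistic_irls,
    robust_logistic,
    select_decorrelated_offers,
    subject_betas,
)
from gobudget.io import LOG_COLUMNS, annotate_states
from gobudget.synth import GroupDesign, generate_subject


def _manual_rows(trials):
    """Build a minimal valid-looking log from (values, actions) trials."""
    rows = []
    for t, (values, actions) in enumerate(trials, start=1):
        n_acc = n_rej = 0
        m = 0
        from gobudget.task import update_m

        for i, (v, a) in enumerate(zip(values, actions), start=1):
            rows.append(
                {
                    "subject_id": 1, "session": 1, "trial": t,
                    "offer_index": i, "offer_value": v, "m_at_offer": m,
                    "action": a, "forced": 0,
                    "n_offers": len(values), "budget": 6,
                }
            )
            m = update_m(m, a, v, i, n_rej)
            if a == "go":
                n_acc += 1
            else:
                n_rej += 1
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


class TestAcceptanceGrid:
    def test_cell_counting_against_brute_force(self, trade3_group):
        """Every grid cell equals a direct recount of the raw records."""
        df, _, _ = trade3_group
        grid = acceptance_grid(df)
        ann = annotate_states(df)
        free = ann[(ann.forced == 0) & (ann.m_at_offer == 0)]
        rng = np.random.default_rng(0)
        sample = grid.sample(n=min(25, len(grid)), random_state=3)
        for row in sample.itertuples():
            cell = free[
                (free.offer_index == row.offer_index)
                & (free.n_rejected_before == row.n_rejected)
                & (free.offer_value == row.offer_value)
            ]
            assert len(cell) == row.n_obs
            assert (cell.action == "go").mean() == pytest.approx(row.p_accept)

    def test_min_count_threshold(self):
        # 20 observations, 12 accepts -> p 0.6, included; 14 obs -> excluded
        trials = []
        for k in range(20):
            action = "go" if k < 12 else "nogo"
            trials.append(([5] * 7, [action] + ["nogo"] * 6))
        for _ in range(14):
            trials.append(([3] * 7, ["nogo"] * 7))
        df = _manual_rows(trials)
        grid = acceptance_grid(df, min_count=15)
        cell5 = grid[(grid.offer_index == 1) & (grid.offer_value == 5)]
        assert cell5.n_obs.item() == 20
        assert cell5.p_accept.item() == pytest.approx(0.6)
        assert bool(cell5.included.item())
        cell3 = grid[(grid.offer_index == 1) & (grid.offer_value == 3)]
        assert cell3.n_obs.item() == 14
        assert not bool(cell3.included.item())

    def test_all_nogo_grid_has_zero_probabilities(self):
        trials = [([3, 5, 7, 3, 5, 7, 3], ["nogo"] * 7) for _ in range(30)]
        grid = acceptance_grid(_manual_rows(trials))
        assert (grid.p_accept == 0).all()

    def test_penalty_states_excluded(self, trade3_group):
        """The grid only summarizes uniform-contingency (m=0) offers."""
        df, _, _ = trade3_group
        grid = acceptance_grid(df)
        ann = annotate_states(df)
        free = ann[(ann.forced == 0) & (ann.m_at_offer == 0)]
        assert grid.n_obs.sum() == len(free)

    def test_empty_dataset_gives_empty_grid(self, trade3_group):
        df, _, _ = trade3_group
        grid = acceptance_grid(df.iloc[0:0])
        assert grid.empty


class TestDecorrelatedSubset:
    def test_selection_rules(self, trade3_group):
        df, _, _ = trade3_group
        sub = select_decorrelated_offers(df)
        assert set(sub.offer_index.unique()) <= {2, 3}
        assert (sub.m_at_offer == 0).all()
        assert (sub.forced == 0).all()
        excluded = annotate_states(df)
        outside = excluded[excluded.offer_index == 5]
        assert not outside.index.isin(sub.index).any()

    def test_subset_invariant_to_row_order(self, trade3_group):
        df, _, _ = trade3_group
        a = select_decorrelated_offers(df)
        b = select_decorrelated_offers(df.sample(frac=1.0, random_state=1))
        cols = ["subject_id", "trial", "offer_index"]
        pd.testing.assert_frame_equal(
            a[cols].reset_index(drop=True), b[cols].reset_index(drop=True)
        )


class TestLogisticIRLS:
    def _simulate(self, rng, n=4000, b=(0.2, 0.5, 0.9)):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        eta = b[0] + b[1] * x1 + b[2] * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return np.column_stack([np.ones(n), x1, x2]), y

    def test_plain_irls_matches_statsmodels(self):
        import statsmodels.api as sm

        X, y = self._simulate(np.random.default_rng(0))
        beta, se, converged = logistic_irls(X, y, robust=False)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert converged
        assert beta == pytest.approx(ref.params, abs=1e-6)
        assert se == pytest.approx(ref.bse, rel=1e-4)

    def test_robust_weights_preserve_sign_and_ordering(self):
        """Down-weighting surprising binary outcomes sharpens (inflates)
        coefficients but cannot change which effects are present or their
        relative strength on clean, well-separated data."""
        X, y = self._simulate(np.random.default_rng(1))
        b_plain, _, _ = logistic_irls(X, y, robust=False)
        b_rob, _, _ = logistic_irls(X, y, robust=True)
        assert np.all(np.sign(b_rob) == np.sign(b_plain))
        assert b_rob[2] > b_rob[1]  # true ordering b_x2 > b_x1 kept
        assert np.all(np.abs(b_rob) >= np.abs(b_plain) * 0.8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(100), np.ones(100)])
        y = np.repeat([0.0, 1.0], 50)
        with pytest.raises(ValueError):
            logistic_irls(X, y)


class TestSubjectRegression:
    def test_both_values_drive_choice_when_generated_jointly(self):
        """trade1 with a mid weight loads positively on IR and EV."""
        design = GroupDesign(
            n_subjects=1, n_sessions=1, trials_per_session=720,
            model_id="trade1", seed=23,
            group_params={"tau": (0.8, 1e-6), "c_int": (5.0, 1e-6), "w": (0.5, 1e-6)},
        )
        df, _ = generate_subject(design, 1)
        fit = robust_logistic(df)
        betas = dict(zip(fit.terms, fit.beta))
        assert betas["IR"] > 0 and betas["EV"] > 0

    def test_coin_flip_choices_give_null_betas(self):
        design = GroupDesign(
            n_subjects=1, n_sessions=1, trials_per_session=360,
            model_id="optimal", seed=29, group_params={"tau": (1e-4, 1e-8)},
        )
        df, _ = generate_subject(design, 1)
        fit = robust_logistic(df)
        for term, b, se in zip(fit.terms, fit.beta, fit.se):
            if term != "intercept":
                assert abs(b) < 3 * se

    def test_constant_regressor_flagged(self, trade3_group):
        df, _, _ = trade3_group
        one = df[df.subject_id == 1]
        ann = annotate_states(one)
        single_value = ann[ann.offer_value == 5]
        with pytest.raises((ValueError, SeparationError)):
            robust_logistic(single_value)

    def test_value_dissociation_between_generators(self):
        """Optimal-model data loads on EV over IR; immediate-model data
        the reverse."""
        common = dict(n_subjects=1, n_sessions=1, trials_per_session=720, seed=37)
        opt_df, _ = generate_subject(
            GroupDesign(model_id="optimal", group_params={"tau": (1.0, 1e-6)},
                        **common), 1
        )
        imm_df, _ = generate_subject(
            GroupDesign(model_id="immediate",
                        group_params={"tau": (0.8, 1e-6), "c_int": (5.0, 1e-6)},
                        **common), 1
        )
        # plain IRLS: the robust weighting can declare a strong
        # single-regressor effect quasi-separated, which is flagged, not fit
        opt_fit = robust_logistic(opt_df, robust=False)
        imm_fit = robust_logistic(imm_df, robust=False)
        b_opt = dict(zip(opt_fit.terms, opt_fit.beta))
        b_imm = dict(zip(imm_fit.terms, imm_fit.beta))
        assert b_opt["EV"] > b_opt["IR"]
        assert b_imm["IR"] > b_imm["EV"]


class TestGroupTest:
    def _betas(self, ir, ev):
        return pd.DataFrame(
            {
                "subject_id": range(1, len(ir) + 1),
                "ok": True, "intercept": 0.0, "IR": ir, "EV": ev,
            }
        )

    def test_symmetric_betas_give_t_zero(self):
        betas = self._betas([-1.0, 1.0, -2.0, 2.0], [-0.5, 0.5, -1.5, 1.5])
        tests = group_ttest(betas)
        for gt in tests:
            assert gt.t == pytest.approx(0.0, abs=1e-12)
            assert gt.p == pytest.approx(1.0)
            assert gt.df == 3

    def test_degenerate_equal_betas_flagged(self):
        betas = self._betas([0.4] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError):
            group_ttest(betas)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            group_ttest(self._betas([1.0], [1.0]))

    def test_group_effects_detected_at_design_scale(self, trade3_group):
        """A 23-subject group generated with both values in play yields
        significant group-level IR and EV effects."""
        df, _, _ = trade3_group
        betas = subject_betas(df)
        tests = {t.term: t for t in group_ttest(betas)}
        assert tests["IR"].df == betas.ok.sum() - 1
        assert tests["IR"].p < 0.05
        assert tests["EV"].p < 0.05
        assert tests["EV"].mean > 0
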