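import warnings

import numpy as np
import pytest

import carecast as cc
from carecast.errors import CarecastError, EstimationError
from carecast.estimation import (
    IntervalMatrixSet,
    LogitCoefficients,
    TransitionCounts,
    _cell_design,
    flag_sparse_cells,
)
from carecast.matrices import absorbing_death_row
from carecast.states import HealthState, default_age_groups


def counts_with_row(row, age=0, state=0) -> TransitionCounts:
    n = np.zeros((5, 4, 5), dtype=int)
    n[:, :, 0] = 1  # keep other rows non-empty
    n[age, state] = row
    return TransitionCounts(n)


class TestCountTransitions:
    def test_empty_panel_gives_all_zero_counts(self, ref_norm):
        panel = cc.simulate_panel(ref_norm, np.zeros((5, 4), dtype=int), seed=0)
        counts = cc.count_transitions(panel)
        assert counts.total() == 0

    def test_single_record(self, ref_norm):
        import pandas as pd

        panel = cc.PanelDataset(
            pd.DataFrame(
                {
                    "id": [1],
                    "age_group": ["65-69"],
                    "state_baseline": ["HEALTHY"],
                    "state_followup": ["DEATH"],
                }
            )
        )
        counts = cc.count_transitions(panel)
        assert counts.n[0, 0, 4] == 1
        assert counts.total() == 1

    def test_matches_brute_force_recount(self, small_panel):
        counts = cc.count_transitions(small_panel)
        # independent oracle: python-level tally over raw records
        oracle = np.zeros((5, 4, 5), dtype=int)
        ages = [g.label for g in default_age_groups()]
        for rec in small_panel.records.itertuples():
            a = ages.index(rec.age_group)
            i = HealthState[rec.state_baseline].index
            j = HealthState[rec.state_followup].index
            oracle[a, i, j] += 1
        assert np.array_equal(counts.n, oracle)
        assert counts.total() == len(small_panel)

    def test_negative_counts_rejected(self):
        with pytest.raises(CarecastError, match="non-negative"):
            TransitionCounts(np.full((5, 4, 5), -1))


class TestEmpiricalMatrix:
    def test_published_mild_65_69_row(self):
        counts = counts_with_row([4, 5, 0, 0, 1], age=0, state=1)
        est = cc.empirical_matrix(counts)
        assert est.probs[0, 1].tolist() == [0.4, 0.5, 0.0, 0.0, 0.1]

    def test_one_hot_rows_without_smoothing(self):
        n = np.zeros((5, 4, 5), dtype=int)
        n[:, :, 3] = 7
        est = cc.empirical_matrix(TransitionCounts(n))
        assert np.array_equal(est.probs[:, :4, 3], np.ones((5, 4)))

    def test_symmetric_smoothing(self):
        counts = counts_with_row([1, 1, 1, 1, 1])
        est = cc.empirical_matrix(counts, smoothing=0.5)
        assert np.allclose(est.probs[0, 0], 0.2)

    def test_empty_row_without_smoothing_names_cell(self):
        n = np.ones((5, 4, 5), dtype=int)
        n[2, 3] = 0
        with pytest.raises(EstimationError, match=r"75-79, SEVERE"):
            cc.empirical_matrix(TransitionCounts(n))

    def test_smoothing_avoids_degenerate_probabilities(self):
        counts = counts_with_row([10, 0, 0, 0, 0])
        est = cc.empirical_matrix(counts, smoothing=0.5)
        assert (est.probs[:, :4, :] > 0).all()
        assert (est.probs[:, :4, :] < 1).all()

    def test_rows_stochastic_and_death_absorbing(self, small_counts):
        est = cc.empirical_matrix(small_counts)
        est.validate(atol=1e-9)

    def test_flag_sparse_cells(self):
        n = np.full((5, 4, 5), 50, dtype=int)
        n[1, 2] = [3, 0, 0, 0, 2]  # small row with exact zeros
        flags = flag_sparse_cells(TransitionCounts(n))
        assert flags == [
            {"age_group": "70-74", "from_state": "MODERATE", "row_total": 5}
        ]


class TestMultinomialLogit:
    def test_saturated_fit_reproduces_empirical_matrix(self, small_panel, small_counts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coefs = cc.fit_multinomial_logit(small_panel, design="saturated")
        pred = cc.predict_matrix(coefs)
        emp = cc.empirical_matrix(small_counts)
        assert np.abs(pred.probs - emp.probs).max() < 1e-6
        assert coefs.converged

    def test_separation_cap_warns_when_reference_outcome_is_empty(self):
        # a cell with all mass on DEATH forces the death contrast onto the
        # +cap bound, so the warning fires deterministically
        n = np.full((5, 4, 5), 20, dtype=int)
        n[0, 3] = [0, 0, 0, 0, 50]
        with pytest.warns(UserWarning, match="separation cap"):
            coefs = cc.fit_multinomial_logit(TransitionCounts(n), design="saturated")
        assert coefs.capped

    def test_null_panel_gives_flat_additive_coefficients(self):
        # follow-up independent of age and baseline state
        probs = np.tile(np.array([0.5, 0.2, 0.1, 0.1, 0.1]), (5, 5, 1))
        probs[:, 4] = absorbing_death_row()
        mset = cc.TransitionMatrixSet(probs)
        panel = cc.simulate_panel(mset, np.full((5, 4), 2000), seed=9)
        coefs = cc.fit_multinomial_logit(panel, design="additive")
        non_intercept = coefs.coef[1:, :]
        assert np.abs(non_intercept).max() < 0.15  # ~ a few standard errors

    def test_counts_input_equivalent_to_panel_input(self, small_panel, small_counts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cc.fit_multinomial_logit(small_panel)
            b = cc.fit_multinomial_logit(small_counts)
        assert np.allclose(a.coef, b.coef, atol=1e-8)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-8)

    def test_empty_panel_rejected(self):
        with pytest.raises(EstimationError, match="empty"):
            cc.fit_multinomial_logit(TransitionCounts(np.zeros((5, 4, 5), dtype=int)))

    def test_single_outcome_level_rejected(self):
        n = np.zeros((5, 4, 5), dtype=int)
        n[:, :, 0] = 10
        with pytest.raises(EstimationError, match="2 observed levels"):
            cc.fit_multinomial_logit(TransitionCounts(n))

    def test_unknown_design_rejected(self, small_counts):
        with pytest.raises(CarecastError, match="unknown design"):
            cc.fit_multinomial_logit(small_counts, design="quadratic")


class TestPredictMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        X, names = _cell_design("additive", default_age_groups())
        coefs = LogitCoefficients(
            design="additive",
            coef=np.zeros((X.shape[1], 4)),
            feature_names=names,
            age_groups=default_age_groups(),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
        )
        pred = cc.predict_matrix(coefs)
        assert np.allclose(pred.probs[:, :4, :], 0.2)

    def test_capped_intercept_concentrates_row_mass(self):
        X, names = _cell_design("additive", default_age_groups())
        coef = np.zeros((X.shape[1], 4))
        coef[0, 3] = 30.0  # huge intercept for the DEATH contrast
        coefs = LogitCoefficients(
            design="additive",
            coef=coef,
            feature_names=names,
            age_groups=default_age_groups(),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
        )
        pred = cc.predict_matrix(coefs)
        assert pred.probs[0, 0, 4] > 1 - 1e-12

    def test_design_mismatch_rejected(self):
        X, names = _cell_design("saturated", default_age_groups())
        coefs = LogitCoefficients(
            design="additive",  # wrong: features come from the saturated design
            coef=np.zeros((X.shape[1], 4)),
            feature_names=names,
            age_groups=default_age_groups(),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
        )
        with pytest.raises(CarecastError, match="design"):
            cc.predict_matrix(coefs)

    def test_rows_sum_to_one_by_construction(self, small_panel):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coefs = cc.fit_multinomial_logit(small_panel, design="additive")
        cc.predict_matrix(coefs).validate(atol=1e-9)


class TestAdditiveRecovery:
    def test_recovers_an_additively_generated_matrix(self):
        # generating matrix built from the additive logit itself, so the
        # design is correctly specified and recovery is meaningful
        X, names = _cell_design("additive", default_age_groups())
        rng = np.random.default_rng(12)
        true = rng.normal(scale=0.6, size=(X.shape[1], 4))
        coefs = LogitCoefficients(
            design="additive",
            coef=true,
            feature_names=names,
            age_groups=default_age_groups(),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
        )
        mset = cc.predict_matrix(coefs)
        panel = cc.simulate_panel(mset, np.full((5, 4), 5000), seed=13)
        fit = cc.fit_multinomial_logit(panel, design="additive")
        pred = cc.predict_matrix(fit)
        assert np.abs(pred.probs - mset.probs).max() < 0.05


class TestProbabilityLimits:
    def test_wald_closed_form_half(self):
        # checked cell has p=0.5, n=100
        n = np.ones((5, 4, 5), dtype=int)
        n[0, 0] = [50, 50, 0, 0, 0]
        limits = cc.probability_limits(TransitionCounts(n), level=0.95, method="wald")
        half_width = 1.959964 * np.sqrt(0.25 / 100)
        assert limits.lower.probs[0, 0, 0] == pytest.approx(0.5 - half_width, abs=1e-6)
        assert limits.upper.probs[0, 0, 0] == pytest.approx(0.5 + half_width, abs=1e-6)

    def test_wald_degenerate_at_observed_zero(self):
        n = np.ones((5, 4, 5), dtype=int)
        n[0, 0] = [10, 0, 0, 0, 0]
        limits = cc.probability_limits(TransitionCounts(n), method="wald")
        assert limits.lower.probs[0, 0, 1] == 0.0
        assert limits.upper.probs[0, 0, 1] == 0.0  # known Wald degeneracy

    def test_empty_row_gets_unit_interval_with_warning(self):
        n = np.ones((5, 4, 5), dtype=int)
        n[3, 2] = 0
        with pytest.warns(UserWarning, match="empty transition row"):
            limits = cc.probability_limits(TransitionCounts(n))
        assert limits.lower.probs[3, 2, :4].tolist() == [0.0] * 4
        assert (limits.upper.probs[3, 2, :4] == 1.0).all()

    def test_limits_bracket_point(self, small_counts):
        for method in ("wald", "bootstrap"):
            limits = cc.probability_limits(
                small_counts, method=method, B=200, seed=0
            )
            assert (limits.lower.probs <= limits.point.probs + 1e-12).all()
            assert (limits.point.probs <= limits.upper.probs + 1e-12).all()

    def test_bootstrap_coverage_close_to_nominal(self):
        # coverage of the generating p for one binomial-style cell
        rng = np.random.default_rng(99)
        p_true, n_row, level = 0.3, 200, 0.9
        hits = 0
        reps = 200
        for _ in range(reps):
            n = np.ones((5, 4, 5), dtype=int)
            n[0, 0] = rng.multinomial(n_row, [p_true, 0.4, 0.1, 0.1, 0.1])
            limits = cc.probability_limits(
                TransitionCounts(n), level=level, method="bootstrap", B=200, seed=rng
            )
            if limits.lower.probs[0, 0, 0] <= p_true <= limits.upper.probs[0, 0, 0]:
                hits += 1
        assert 0.8 <= hits / reps <= 0.98

    def test_invalid_level_and_method_rejected(self, small_counts):
        with pytest.raises(CarecastError, match="level"):
            cc.probability_limits(small_counts, level=1.2)
        with pytest.raises(CarecastError, match="method"):
            cc.probability_limits(small_counts, method="jackknife")
        with pytest.raises(CarecastError, match="B >= 100"):
            cc.probability_limits(small_counts, method="bootstrap", B=10)

    def test_interval_set_ordering_enforced(self, ref_matrices):
        with pytest.raises(CarecastError, match="lower <= point"):
            IntervalMatrixSet(
                point=ref_matrices,
                lower=ref_matrices.normalized(),
                upper=ref_matrices,
                level=0.95,
                method="wald",
            )
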