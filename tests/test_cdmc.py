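"""Likelihood, fitting, information criteria and Wald inference checks.

The saturated fit has a closed-form oracle (empirical cell proportions);
the Newton optimizer is checked against it, and the additive fit against
an independent multinomial-logit implementation (statsmodels).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from affectmc import (
    CDMCParameters,
    EmotionState,
    GeneratorConfig,
    InteractionSequence,
    QualityLevel,
    TransitionData,
    count_free_parameters,
    empirical_transition_matrices,
    extract_transitions,
    fit_cdmc,
    information_criteria,
    log_likelihood,
    select_order,
    simulate_sequences,
    transition_probabilities,
    wald_statistics,
)
from affectmc.cdmc import COEF_CAP, all_contexts, context_index
from affectmc.core_io import TransitionRecord
from affectmc.synthetic_data import second_order_kernels

N, U, P = EmotionState.NEGATIVE, EmotionState.NEUTRAL, EmotionState.POSITIVE
LO, ME, HI = QualityLevel.LOW, QualityLevel.MEDIUM, QualityLevel.HIGH


def records_from_counts(counts, order=1):
    """counts: {(context tuple, quality): [n_neg, n_neu, n_pos]}"""
    recs = []
    for (ctx, q), row in counts.items():
        for j, n in enumerate(row):
            recs.extend(
                TransitionRecord(tuple(ctx), q, EmotionState(j), None)
                for _ in range(n)
            )
    return TransitionData(order=order, records=recs)


def full_grid_counts(fill):
    """Counts with every (context, quality) cell populated identically."""
    return {
        ((s,), q): list(fill)
        for s in EmotionState
        for q in QualityLevel
    }


class TestCountFreeParameters:
    @pytest.mark.parametrize(
        "order,n_states,n_quality,param,expected",
        [
            (1, 3, 3, "saturated", 18),
            (2, 3, 3, "saturated", 54),
            (1, 2, 1, "saturated", 2),
            (1, 3, 3, "additive", 10),
            (2, 3, 3, "additive", 22),
        ],
    )
    def test_known_counts(self, order, n_states, n_quality, param, expected):
        assert count_free_parameters(order, n_states, n_quality, param) == expected

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            count_free_parameters(0, 3, 3, "saturated")
        with pytest.raises(ValueError):
            count_free_parameters(1, 1, 3, "saturated")
        with pytest.raises(ValueError):
            count_free_parameters(1, 3, 3, "ridge")

    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("param", ["saturated", "additive"])
    def test_count_equals_stored_coefficients(self, order, param):
        k = count_free_parameters(order, 3, 3, param)
        shape_rows = k // 2
        params = CDMCParameters(
            order=order, parameterization=param,
            coef=np.zeros((shape_rows, 2)),
        )
        assert params.coef.size == k
        assert len(params.feature_names()) * 2 == k


class TestTransitionProbabilities:
    def zero_params(self, param="saturated", order=1):
        rows = count_free_parameters(order, 3, 3, param) // 2
        return CDMCParameters(order=order, parameterization=param,
                              coef=np.zeros((rows, 2)))

    def test_zero_coefficients_give_uniform_row(self):
        p = transition_probabilities(self.zero_params(), (U,), HI)
        assert np.allclose(p, [1 / 3, 1 / 3, 1 / 3])

    def test_hand_computed_softmax(self):
        # predictors (ln2, 0, ln2) -> probabilities (0.4, 0.2, 0.4)
        params = self.zero_params()
        i = context_index((U,))
        params.coef[i * 3, :] = [math.log(2), math.log(2)]
        p = transition_probabilities(params, (U,), HI)
        assert np.allclose(p, [0.4, 0.2, 0.4], atol=1e-12)

    def test_rows_sum_to_one_and_are_positive(self):
        rng = np.random.default_rng(5)
        for param in ("saturated", "additive"):
            rows = count_free_parameters(1, 3, 3, param) // 2
            params = CDMCParameters(
                order=1, parameterization=param,
                coef=rng.normal(0, 2, (rows, 2)),
            )
            for s in EmotionState:
                for q in QualityLevel:
                    p = transition_probabilities(params, (s,), q)
                    assert abs(p.sum() - 1) < 1e-12
                    assert np.all(p > 0)

    def test_context_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            transition_probabilities(self.zero_params(), (U, N), HI)


class TestLogLikelihood:
    def test_empty_data_is_zero(self):
        params = TestTransitionProbabilities().zero_params()
        assert log_likelihood(params, TransitionData(1, [])) == 0.0

    def test_uniform_model_sums_log_third(self):
        params = TestTransitionProbabilities().zero_params()
        data = records_from_counts({((U,), LO): [4, 3, 3]})
        assert log_likelihood(params, data) == pytest.approx(10 * math.log(1 / 3))

    def test_single_record_half_probability(self):
        params = TestTransitionProbabilities().zero_params()
        i = context_index((U,))
        # predictors (ln2, 0, ln2): P(negative) = 0.4 -> tweak to get 0.5:
        # predictors (ln2, 0, 0) give (0.5, 0.25, 0.25)
        params.coef[i * 3, 0] = math.log(2)
        data = records_from_counts({((U,), HI): [1, 0, 0]})
        assert log_likelihood(params, data) == pytest.approx(math.log(0.5))

    def test_brute_force_per_record_sum(self, study_corpus):
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        fit = fit_cdmc(data)
        brute = sum(
            math.log(
                transition_probabilities(fit.params, r.context, r.quality)[int(r.next)]
            )
            for r in data.records
        )
        assert log_likelihood(fit.params, data) == pytest.approx(brute, abs=1e-8)


class TestSaturatedFit:
    def test_cell_proportion_oracle(self):
        counts = full_grid_counts([2, 2, 2])
        counts[((U,), LO)] = [46, 5, 1]
        fit = fit_cdmc(records_from_counts(counts))
        p = transition_probabilities(fit.params, (U,), LO)
        assert p[int(N)] == pytest.approx(46 / 52, abs=1e-10)
        assert p[int(U)] == pytest.approx(5 / 52, abs=1e-10)
        # all-equal cells stay uniform
        q = transition_probabilities(fit.params, (P,), HI)
        assert np.allclose(q, 1 / 3, atol=1e-10)

    def test_equal_counts_give_zero_coefficients(self):
        fit = fit_cdmc(records_from_counts(full_grid_counts([7, 7, 7])))
        assert np.allclose(fit.params.coef, 0, atol=1e-12)

    def test_optimizer_matches_closed_form(self, study_corpus):
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        closed = fit_cdmc(data, method="closed_form")
        newton = fit_cdmc(data, method="newton")
        assert np.max(np.abs(closed.params.coef - newton.params.coef)) < 1e-6
        assert newton.logL == pytest.approx(closed.logL, abs=1e-8)

    def test_logl_equals_count_weighted_log_proportions(self, study_corpus):
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        fit = fit_cdmc(data)
        emp = empirical_transition_matrices(data)
        expected = 0.0
        for key, counts in emp.support.items():
            nz = counts > 0
            if nz.any():
                expected += counts[nz] @ np.log(emp.matrices[key][nz])
        assert fit.logL == pytest.approx(expected, abs=1e-8)

    def test_quasi_separation_capped_and_flagged(self):
        counts = full_grid_counts([3, 3, 3])
        counts[((U,), LO)] = [12, 4, 0]  # positive never observed in this cell
        fit = fit_cdmc(records_from_counts(counts))
        assert any("separation" in f for f in fit.separation)
        assert np.max(np.abs(fit.params.coef)) <= COEF_CAP + 1e-9

    def test_monte_carlo_parameter_recovery(self):
        cfg = GeneratorConfig(seed=42, n_participants_per_group=300,
                              length_range=(20, 20))
        sequences = simulate_sequences(cfg)
        low = [s for s in sequences if s.participant_id <= "P300"]
        data = extract_transitions(low, 1)
        fit = fit_cdmc(data)
        worst = 0.0
        for q in QualityLevel:
            for ctx in all_contexts(1):
                p_hat = transition_probabilities(fit.params, ctx, q)
                p_true = cfg.kernels[list(cfg.kernels)[0]][q][context_index(ctx)]
                worst = max(worst, float(np.max(np.abs(p_hat - p_true))))
        assert worst < 0.08

    def test_error_shrinks_with_sample_size(self):
        kernel = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.3, 0.6]])

        def max_error(n_per, seed):
            rng = np.random.default_rng(seed)
            counts = {
                ((s,), q): list(rng.multinomial(n_per, kernel[int(s)]))
                for s in EmotionState for q in QualityLevel
            }
            fit = fit_cdmc(records_from_counts(counts))
            return max(
                float(np.max(np.abs(
                    transition_probabilities(fit.params, (s,), q) - kernel[int(s)]
                )))
                for s in EmotionState for q in QualityLevel
            )

        errors = [
            np.mean([max_error(n_per, seed) for seed in range(5)])
            for n_per in (500, 2000, 8000)
        ]
        assert errors[0] > errors[1] > errors[2]


class TestAdditiveFit:
    def test_additive_likelihood_never_exceeds_saturated(self, study_corpus):
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        sat = fit_cdmc(data, parameterization="saturated")
        add = fit_cdmc(data, parameterization="additive")
        assert add.logL <= sat.logL + 1e-8
        assert add.k == 10

    def test_agrees_with_statsmodels_mnlogit(self, study_corpus):
        sm = pytest.importorskip("statsmodels.api")
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        fit = fit_cdmc(data, parameterization="additive")

        # identical design: reference outcome first so MNLogit pins it at 0
        y = np.array([
            0 if r.next is U else (1 if r.next is N else 2) for r in data.records
        ])
        X = np.column_stack([
            [1.0 if r.context[0] is U else 0.0 for r in data.records],
            [1.0 if r.context[0] is P else 0.0 for r in data.records],
            [1.0 if r.quality is LO else 0.0 for r in data.records],
            [1.0 if r.quality is ME else 0.0 for r in data.records],
            np.ones(len(data.records)),
        ])
        res = sm.MNLogit(y, X).fit(disp=0, method="newton")
        assert fit.logL == pytest.approx(res.llf, abs=1e-6)
        ours = fit.params.coef  # rows: Xt=neutral, Xt=positive, Zt=low, Zt=med, const
        theirs = res.params.to_numpy() if hasattr(res.params, "to_numpy") else res.params
        assert np.allclose(ours, theirs, atol=1e-4)

    def test_wald_se_agree_with_statsmodels(self, study_corpus):
        sm = pytest.importorskip("statsmodels.api")
        _, sequences = study_corpus
        data = extract_transitions(sequences, 1)
        fit = fit_cdmc(data, parameterization="additive")
        table = wald_statistics(fit)

        y = np.array([
            0 if r.next is U else (1 if r.next is N else 2) for r in data.records
        ])
        X = np.column_stack([
            [1.0 if r.context[0] is U else 0.0 for r in data.records],
            [1.0 if r.context[0] is P else 0.0 for r in data.records],
            [1.0 if r.quality is LO else 0.0 for r in data.records],
            [1.0 if r.quality is ME else 0.0 for r in data.records],
            np.ones(len(data.records)),
        ])
        res = sm.MNLogit(y, X).fit(disp=0, method="newton")
        theirs = np.asarray(res.bse)  # (5 features, 2 outcomes)
        ours = table["se"].to_numpy().reshape(2, 5).T
        assert np.allclose(ours, theirs, atol=1e-4)


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "logL,k,n,aic,bic",
        [
            (-691.08, 18, 880, 1418.16, 1504.20),
            (-662.59, 54, 788, 1433.18, 1685.33),
            (0.0, 0, 10, 0.0, 0.0),
        ],
    )
    def test_printed_triples_reproduced(self, logL, k, n, aic, bic):
        got_aic, got_bic = information_criteria(logL, k, n)
        assert got_aic == pytest.approx(aic, abs=0.005)
        assert got_bic == pytest.approx(bic, abs=0.005)

    def test_first_order_bic_gap(self):
        _, bic1 = information_criteria(-691.08, 18, 880)
        _, bic2 = information_criteria(-662.59, 54, 788)
        assert bic2 - bic1 == pytest.approx(181.1, abs=0.05)

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 0)


class TestSelectOrder:
    def test_first_order_generator_prefers_order_one(self, study_corpus):
        _, sequences = study_corpus
        table = select_order(sequences, orders=(1, 2))
        assert int(table.loc[table["preferred"], "order"].iloc[0]) == 1
        assert table.loc[table["order"] == 2, "deltaBIC"].iloc[0] > 10

    def test_second_order_generator_prefers_order_two(self):
        cfg = GeneratorConfig(
            seed=3, order=2, kernels=second_order_kernels(0.8),
            n_participants_per_group=60, length_range=(18, 18),
        )
        sequences = simulate_sequences(cfg)
        table = select_order(sequences, orders=(1, 2))
        assert int(table.loc[table["preferred"], "order"].iloc[0]) == 2
        assert table.loc[table["order"] == 1, "deltaBIC"].iloc[0] > 10

    def test_deterministic_given_fixed_input(self, study_corpus):
        _, sequences = study_corpus
        t1 = select_order(sequences)
        t2 = select_order(sequences)
        pd.testing.assert_frame_equal(t1, t2)

    def test_n_is_order_specific(self, study_corpus):
        _, sequences = study_corpus
        table = select_order(sequences)
        n1 = int(table.loc[table["order"] == 1, "n"].iloc[0])
        n2 = int(table.loc[table["order"] == 2, "n"].iloc[0])
        assert n1 - n2 == len(sequences)


class TestWaldStatistics:
    def _fit_with_vcov(self, est, se):
        """Minimal converged fit carrying one designated coefficient."""
        rows = 5
        coef = np.zeros((rows, 2))
        coef[0, 0] = est
        params = CDMCParameters(order=1, parameterization="additive", coef=coef)
        from affectmc.cdmc import FitResult, information_criteria

        vcov = np.eye(rows * 2) * se**2
        aic, bic = information_criteria(-10.0, 10, 50)
        return FitResult(params=params, logL=-10.0, k=10, n=50,
                         aic=aic, bic=bic, vcov=vcov, converged=True)

    def test_direct_formula(self):
        table = wald_statistics(self._fit_with_vcov(2.0, 1.0))
        row = table.iloc[0]
        assert row["z"] == pytest.approx(2.0)
        assert row["ci_lower"] == pytest.approx(0.0400, abs=5e-4)
        assert row["ci_upper"] == pytest.approx(3.9600, abs=5e-4)

    def test_published_low_quality_coefficient_row(self):
        # printed regression row: estimate 3.5019, SD 0.604 -> z 5.802
        table = wald_statistics(self._fit_with_vcov(3.5019, 0.604))
        row = table.iloc[0]
        assert row["z"] == pytest.approx(5.80, abs=0.01)
        assert row["ci_lower"] == pytest.approx(2.318, abs=2e-3)
        assert row["ci_upper"] == pytest.approx(4.686, abs=2e-3)

    def test_null_coefficient(self):
        table = wald_statistics(self._fit_with_vcov(0.0, 0.7))
        row = table.iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_non_positive_variance_flagged(self):
        fit = self._fit_with_vcov(1.0, 1.0)
        fit.vcov[0, 0] = -1.0
        table = wald_statistics(fit)
        assert bool(table.iloc[0]["flagged"])
        assert not table.iloc[1:]["flagged"].any()


class TestEmpiricalMatrices:
    def test_uniform_counts(self):
        data = records_from_counts({((U,), LO): [10, 10, 10]})
        mats = empirical_transition_matrices(data)
        assert np.allclose(mats.row(LO, (U,)), 1 / 3)

    def test_published_neutral_persistence_ratio(self):
        # 32 of 41 records stay neutral -> 78.05%
        data = records_from_counts({((U,), LO): [9, 32, 0]})
        mats = empirical_transition_matrices(data)
        row = mats.row(LO, (U,))
        assert row[int(U)] == pytest.approx(0.7805, abs=5e-5)
        assert row[int(P)] == 0.0

    def test_zero_support_row_flagged_undefined(self):
        data = records_from_counts({((U,), LO): [1, 1, 1]})
        mats = empirical_transition_matrices(data)
        assert not mats.defined[(HI, (P,))]
        assert np.all(np.isnan(mats.matrices[(HI, (P,))]))

    def test_smoothing_fills_zero_cells(self):
        data = records_from_counts({((U,), LO): [1, 1, 1]})
        mats = empirical_transition_matrices(data, smoothing=0.5)
        assert mats.defined[(HI, (P,))]
        assert np.allclose(mats.row(HI, (P,)), 1 / 3)

    def test_defined_rows_sum_to_one(self, study_corpus):
        _, sequences = study_corpus
        mats = empirical_transition_matrices(extract_transitions(sequences, 1))
        for key, row in mats.matrices.items():
            if mats.defined[key]:
                assert abs(row.sum() - 1) < 1e-12
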