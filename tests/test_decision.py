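"""Decision-curve and monetary model against explicit confusion-matrix oracles."""

import numpy as np
import pytest

from fittriage.decision import (
    CostModel,
    dca_curve,
    monetary_curve,
    optimal_band,
    prob_to_fit,
    steepest_declines,
)
from fittriage.models import fit_logistic
from conftest import build_cohort, random_cohort


def brute_force_dca(probs, y, pt_grid):
    """Explicit confusion matrix at every threshold probability."""
    n = len(y)
    out = []
    for p in pt_grid:
        if p >= 1.0:
            out.append(0.0)
            continue
        tp = fp = 0
        for prob, label in zip(probs, y):
            if prob >= p:
                if label:
                    tp += 1
                else:
                    fp += 1
        out.append(tp / n - (fp / n) * p / (1 - p))
    return np.array(out)


class TestDCACurve:
    def test_treat_none_is_zero_and_treat_all_starts_at_prevalence(self, rng):
        cohort = random_cohort(rng, n=300)
        dca = dca_curve(cohort)
        assert (dca.net_benefit_none == 0).all()
        assert dca.net_benefit_all[0] == pytest.approx(dca.prevalence)
        assert np.nanmax(dca.net_benefit_model) <= dca.prevalence + 1e-12

    def test_perfectly_separating_probabilities_formula(self):
        # 3 events with probability 0.9, 7 non-events at 0.05: at p_t = 0.2
        # everything classified positive is a true positive, NB = 3/10.
        cohort = build_cohort(np.arange(1.0, 11.0), [0] * 7 + [1] * 3)
        probs = np.r_[np.full(7, 0.05), np.full(3, 0.9)]
        dca = dca_curve(cohort, probabilities=probs)
        i = np.flatnonzero(np.isclose(dca.thresholds, 0.2))[0]
        assert dca.net_benefit_model[i] == pytest.approx(0.3)

    def test_endpoint_conventions(self, rng):
        dca = dca_curve(random_cohort(rng, n=200))
        assert dca.net_benefit_model[-1] == 0.0  # p_t = 1: classify none
        assert np.isnan(dca.net_benefit_all[-1])
        assert np.isnan(dca.fit_at_threshold[0]) and np.isnan(dca.fit_at_threshold[-1])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n=int(rng.integers(30, 500)))
        dca = dca_curve(cohort)
        oracle = brute_force_dca(dca.model.predicted, cohort.urgent, dca.thresholds)
        np.testing.assert_allclose(dca.net_benefit_model, oracle, atol=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            dca_curve(build_cohort([1.0, 2.0, 3.0], [1, 1, 1]))

    def test_fit_mapping_consistent_with_model(self, rng):
        cohort = random_cohort(rng, n=400)
        dca = dca_curve(cohort)
        i = 30  # p_t = 0.30
        fit_t = dca.fit_at_threshold[i]
        back = prob_to_fit(dca.model, dca.thresholds[i])
        assert fit_t == pytest.approx(back, rel=1e-12)


class TestProbToFIT:
    def test_worked_inversion(self):
        class M:
            terms = {"const": -2.0, "fit_value": 0.01}

        assert prob_to_fit(M(), 0.5) == pytest.approx(200.0)

    def test_round_trip_identity(self, rng):
        fit = np.round(rng.exponential(40, 500) + 1, 1)
        urgent = rng.random(500) < 1 / (1 + np.exp(1.5 - 0.02 * fit))
        model = fit_logistic(build_cohort(fit, urgent), predictors=("fit_value",))
        for x_star in (5.0, 40.0, 250.0):
            p = 1 / (1 + np.exp(-(model.terms["const"] + model.terms["fit_value"] * x_star)))
            assert prob_to_fit(model, p) == pytest.approx(x_star, rel=1e-9)

    def test_non_positive_slope_errors(self):
        class M:
            terms = {"const": 0.0, "fit_value": 0.0}

        with pytest.raises(ValueError, match="slope"):
            prob_to_fit(M(), 0.5)

    @pytest.mark.parametrize("pt", [0.0, 1.0])
    def test_degenerate_probability_errors(self, pt):
        class M:
            terms = {"const": -2.0, "fit_value": 0.01}

        with pytest.raises(ValueError):
            prob_to_fit(M(), pt)


class TestCostModel:
    def test_default_capsule_price_linkage(self):
        costs = CostModel(cost_colonoscopy=1000.0)
        assert costs.cost_cce == pytest.approx(830.0)
        assert costs.loss_fp == pytest.approx(170.0)
        assert costs.loss_fn == pytest.approx(830.0)  # incremental reading

    def test_absolute_false_negative_reading(self):
        costs = CostModel(cost_colonoscopy=1000.0, fn_absolute=True)
        assert costs.loss_fn == pytest.approx(1830.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            CostModel(cost_colonoscopy=-1.0)


class TestMonetaryCurve:
    def test_zero_costs_give_zero_curve(self, rng):
        cohort = random_cohort(rng, n=100)
        curve = monetary_curve(cohort, CostModel.zero(), np.arange(1.0, 50.0))
        assert (curve.net_benefit_gbp == 0).all()

    def test_worked_four_patient_example(self):
        # FITs {5, 5, 50, 50}, urgent {F, T, F, T}, threshold 20:
        # TP=1 (urgent above), FP=1, TN=1, FN=1 ->
        # (100 + 100 - 17 - 183)/4 = 0.0 GBP
        cohort = build_cohort([5.0, 5.0, 50.0, 50.0], [0, 1, 0, 1])
        costs = CostModel(value_tp=100.0, value_tn=100.0, loss_fp=17.0, loss_fn=183.0)
        curve = monetary_curve(cohort, costs, [20.0])
        assert curve.net_benefit_gbp[0] == 0.0
        assert curve.counts.iloc[0].to_dict() == {"tp": 1, "fp": 1, "tn": 1, "fn": 1}

    def test_true_negative_only_cohort(self):
        cohort = build_cohort([5.0, 8.0, 3.0], [0, 0, 0])
        costs = CostModel(cost_colonoscopy=100.0)
        curve = monetary_curve(cohort, costs, [10.0])
        assert curve.net_benefit_gbp[0] == pytest.approx(costs.value_tn)

    def test_affine_in_each_cost_component(self, rng):
        cohort = random_cohort(rng, n=150)
        grid = np.arange(1.0, 100.0, 5.0)
        base = CostModel(value_tp=10.0, value_tn=20.0, loss_fp=5.0, loss_fn=30.0)
        nb0 = monetary_curve(cohort, base, grid).net_benefit_gbp
        # doubling the whole cost vector doubles the curve
        nb2 = monetary_curve(cohort, base.scaled(2.0), grid).net_benefit_gbp
        np.testing.assert_allclose(nb2, 2 * nb0, atol=1e-12)
        # finite difference in one component is linear with the cell count
        bumped = CostModel(value_tp=11.0, value_tn=20.0, loss_fp=5.0, loss_fn=30.0)
        nb1 = monetary_curve(cohort, bumped, grid).net_benefit_gbp
        tp = monetary_curve(cohort, base, grid).counts["tp"].to_numpy()
        np.testing.assert_allclose(nb1 - nb0, tp / cohort.n, atol=1e-12)

    def test_no_false_negative_loss_makes_curve_monotone(self, rng):
        cohort = random_cohort(rng, n=200)
        costs = CostModel(value_tp=0.0, value_tn=0.0, loss_fp=10.0, loss_fn=0.0)
        nb = monetary_curve(cohort, costs, np.arange(1.0, 200.0)).net_benefit_gbp
        assert (np.diff(nb) >= -1e-12).all()

    def test_empty_grid_errors(self, rng):
        with pytest.raises(ValueError):
            monetary_curve(random_cohort(rng, n=10), CostModel(), [])


class TestSteepestDeclines:
    def make_curve(self, nb, grid=None):
        from fittriage.decision import MonetaryCurve
        import pandas as pd

        nb = np.asarray(nb, dtype=float)
        grid = np.arange(1.0, len(nb) + 1.0) if grid is None else np.asarray(grid)
        return MonetaryCurve(
            fit_grid=grid, net_benefit_gbp=nb,
            counts=pd.DataFrame({"tp": np.zeros(len(nb), dtype=int)}),
            costs=CostModel.zero(), n=1,
        )

    def test_worked_example(self):
        curve = self.make_curve([10, 9, 9, 3, 3])
        assert steepest_declines(curve, k=2) == [(4.0, 6.0), (2.0, 1.0)]

    def test_monotone_curve_has_no_declines(self):
        assert steepest_declines(self.make_curve([1, 2, 2, 5]), k=3) == []

    def test_k_truncates_and_ties_break_low(self):
        curve = self.make_curve([5, 4, 5, 4])
        assert steepest_declines(curve, k=5) == [(2.0, 1.0), (4.0, 1.0)]
        assert steepest_declines(curve, k=1) == [(2.0, 1.0)]

    def test_invalid_k_errors(self):
        with pytest.raises(ValueError):
            steepest_declines(self.make_curve([1, 2]), k=0)


class TestOptimalBand:
    def test_constant_probability_model_has_no_band(self, rng):
        # A flat risk score replicates treat-all (below c) or treat-none
        # (above c) and never strictly beats both.
        cohort = random_cohort(rng, n=100)
        probs = np.full(cohort.n, cohort.urgent.mean())
        band = optimal_band(dca_curve(cohort, probabilities=probs))
        assert band is None

    def test_separating_model_band_covers_interior(self):
        n = 10
        cohort = build_cohort(np.arange(1.0, 11.0), [0] * 7 + [1] * 3)
        probs = np.r_[np.full(7, 0.01), np.full(3, 0.99)]
        dca = dca_curve(cohort, probabilities=probs)
        band = optimal_band(dca)
        assert band is not None
        assert band.p_low <= 0.05
        assert band.p_high >= 0.95
        assert band.argmax_net_benefit == pytest.approx(0.3)

    def test_argmax_inside_band(self, rng):
        cohort = random_cohort(rng, n=500)
        dca = dca_curve(cohort)
        band = optimal_band(dca)
        if band is None:
            pytest.skip("model never beats references on this draw")
        assert band.p_low <= band.argmax_p <= band.p_high
        assert band.p_low <= dca.best_threshold <= band.p_high
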