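"""ROC/AUC against pair-counting oracles; logistic fits against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fittriage.models import (
    SeparationError,
    adjusted_roc,
    compare_auc_paired,
    fit_logistic,
    roc_with_ci,
)
from conftest import build_cohort


def auc_pair_counting(scores, labels):
    """Exhaustive concordance over all positive x negative pairs, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        r = roc_with_ci([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.ci_high == 1.0

    def test_all_ties_give_half(self):
        r = roc_with_ci([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_small_example_matches_pair_counting(self):
        scores = [10, 20, 15, 30, 5]
        labels = [0, 1, 0, 1, 0]
        assert roc_with_ci(scores, labels).auc == auc_pair_counting(scores, labels)

    @given(
        scores=st.lists(st.integers(min_value=0, max_value=30), min_size=4, max_size=60),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_auc_equals_pair_counting_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        got = roc_with_ci(scores, labels).auc
        assert got == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_label_flip_maps_auc_to_complement(self, rng):
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        r = roc_with_ci(scores, labels)
        flipped = roc_with_ci(scores, ~labels)
        assert flipped.auc == pytest.approx(1 - r.auc, abs=1e-12)
        assert flipped.ci_low == pytest.approx(1 - r.ci_high, abs=1e-9)
        assert flipped.ci_high == pytest.approx(1 - r.ci_low, abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            roc_with_ci([1, 2, 3], [1, 1, 1])

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=120)
        labels = rng.random(120) < 0.5
        c = roc_with_ci(scores, labels).curve
        assert (c.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (c.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (np.diff(c["fpr"]) >= 0).all() and (np.diff(c["tpr"]) >= 0).all()

    def test_bootstrap_ci_close_to_delong(self, rng):
        scores = rng.normal(size=400) + rng.random(400)
        labels = rng.random(400) < 0.4
        d = roc_with_ci(scores, labels, method="delong")
        b = roc_with_ci(scores, labels, method="bootstrap", n_boot=500, seed=1)
        assert b.auc == d.auc
        assert abs((b.ci_high - b.ci_low) - (d.ci_high - d.ci_low)) < 0.05

    def test_delong_ci_width_shrinks_with_n(self):
        # Width should fall roughly as 1/sqrt(n) on nested cohorts.
        rng = np.random.default_rng(5)
        scores = rng.normal(size=3200) + 0.8 * (rng.random(3200) < 0.3)
        labels = np.zeros(3200, dtype=bool)
        labels[: int(0.3 * 3200)] = True
        rng.shuffle(labels)
        widths = []
        for n in (200, 800, 3200):
            r = roc_with_ci(scores[:n], labels[:n])
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] > 2.0  # ~4x data halves the width twice


class TestPairedComparison:
    def test_identical_scores(self, rng):
        s = rng.normal(size=100)
        y = rng.random(100) < 0.5
        delta, p = compare_auc_paired(s, s, y)
        assert delta == 0 and p == 1.0

    def test_rank_preserving_transform_has_zero_delta(self, rng):
        s = rng.normal(size=200)
        y = rng.random(200) < 0.4
        delta, p = compare_auc_paired(s, np.exp(s), y)
        assert delta == pytest.approx(0, abs=1e-12)
        assert p == 1.0

    def test_delta_matches_brute_force_difference(self, rng):
        a = rng.integers(0, 10, 40).astype(float)
        b = rng.integers(0, 10, 40).astype(float)
        y = np.zeros(40, dtype=bool)
        y[:15] = True
        delta, _ = compare_auc_paired(a, b, y)
        assert delta == pytest.approx(
            auc_pair_counting(b, y) - auc_pair_counting(a, y), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            compare_auc_paired([1, 2], [1, 2, 3], [0, 1, 1])


class TestLogistic:
    def test_binary_predictor_matches_cross_product_ratio(self, rng):
        # exposed: 10 events / 90 non-events; unexposed: 5 / 95
        exposed = np.repeat([1.0, 0.0], [100, 100])
        urgent = np.r_[np.ones(10), np.zeros(90), np.ones(5), np.zeros(95)].astype(bool)
        cohort = build_cohort(np.full(200, 20.0), urgent, exposed=exposed)
        fit = fit_logistic(cohort, predictors=("exposed",))
        expected_or = (10 * 95) / (90 * 5)
        assert fit.odds_ratios["exposed"] == pytest.approx(expected_or, rel=1e-6)
        assert 0 < fit.p_values["exposed"] < 1
        assert (fit.predicted > 0).all() and (fit.predicted < 1).all()

    def test_zero_variance_predictor_errors(self):
        cohort = build_cohort([10, 20, 30, 40], [0, 0, 1, 1], exposed=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="exposed"):
            fit_logistic(cohort, predictors=("exposed",))

    def test_single_class_outcome_errors(self):
        cohort = build_cohort([10, 20, 30, 40], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(cohort, predictors=("fit_value",))

    def test_complete_separation_diagnosed(self):
        fit = np.r_[np.linspace(1, 5, 30), np.linspace(50, 60, 30)]
        urgent = np.r_[np.zeros(30), np.ones(30)].astype(bool)
        cohort = build_cohort(fit, urgent)
        with pytest.raises(SeparationError):
            fit_logistic(cohort, predictors=("fit_value",))

    def test_wald_interval_contains_odds_ratio(self, rng):
        fit = rng.exponential(30, 500) + 1
        urgent = rng.random(500) < 1 / (1 + np.exp(2 - 0.02 * fit))
        if urgent.all() or not urgent.any():
            pytest.skip("degenerate draw")
        res = fit_logistic(build_cohort(fit, urgent), predictors=("fit_value",))
        row = res.table.loc["fit_value"]
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]


class TestAdjustedROC:
    def test_fit_only_model_reproduces_raw_auc(self, rng):
        fit = rng.exponential(30, 400) + 1
        urgent = rng.random(400) < 1 / (1 + np.exp(1.5 - 0.02 * fit))
        cohort = build_cohort(fit, urgent)
        raw = roc_with_ci(cohort.fit_values, cohort.urgent)
        adj = adjusted_roc(cohort, predictors=("fit_value",))
        assert adj.auc == pytest.approx(raw.auc, abs=1e-12)
        assert adj.apparent

    def test_informative_covariate_raises_adjusted_auc(self, rng):
        # FIT carries no signal; haemoglobin does.  The multivariable model
        # must beat the FIT-only score.
        n = 20000
        fit = rng.exponential(30, n) + 1
        hb = rng.normal(112, 19, n)
        urgent = rng.random(n) < 1 / (1 + np.exp(-(-0.08) * (hb - 95)))
        cohort = build_cohort(fit, urgent, haemoglobin=hb, age=rng.uniform(30, 90, n))
        unadjusted = roc_with_ci(cohort.fit_values, cohort.urgent).auc
        adjusted = adjusted_roc(cohort).auc
        assert adjusted > unadjusted + 0.1

    def test_single_class_outcome_errors(self):
        cohort = build_cohort([10, 20, 30], [0, 0, 0])
        with pytest.raises(ValueError):
            adjusted_roc(cohort)
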