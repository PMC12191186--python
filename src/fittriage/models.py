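"""ROC/AUC estimation, logistic regression, and paired AUC comparison.

The AUC is computed as the Mann–Whitney concordance probability with ties
counted 1/2 — important here because censored-FIT imputation stacks mass at
the 7, 10 and 400 µg/g detection limits.  Confidence intervals use DeLong's
structural-components estimator (computed with the midrank algorithm of Sun &
Xu) by default, or a seeded percentile bootstrap.  Logistic models are fitted
by maximum likelihood via statsmodels, reported as odds ratios with Wald 95%
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortTable

__all__ = [
    "ROCResult",
    "LogisticFit",
    "SeparationError",
    "roc_with_ci",
    "compare_auc_paired",
    "fit_logistic",
    "adjusted_roc",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows complete or quasi-complete separation."""


@dataclass(frozen=True)
class ROCResult:
    """AUC with a 95% interval and the full ROC curve.

    ``curve`` holds (fpr, tpr, threshold) triples, starting at (0, 0) and
    ending at (1, 1).  ``apparent`` marks in-sample (non-cross-validated)
    performance of a fitted model.
    """

    auc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame
    method: str = "delong"
    n_pos: int = 0
    n_neg: int = 0
    apparent: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError(
                f"inconsistent AUC interval: {self.ci_low} <= {self.auc} <= {self.ci_high}"
            )

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "apparent": self.apparent,
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("AUC undefined: labels contain a single class")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (positives) and V01 (negatives).

    AUC = mean(V10) = mean(V01); their empirical variances give the DeLong
    variance estimate.
    """
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    v10, _ = _delong_components(scores, y)
    return float(np.mean(v10))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    v10, v01 = _delong_components(scores, y)
    auc = float(np.mean(v10))
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def roc_with_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with a 95% confidence interval.

    ``method`` is ``"delong"`` (analytic, deterministic; the default) or
    ``"bootstrap"`` (seeded stratified percentile bootstrap).  Ties in the
    scores contribute 1/2 to the concordance.
    """
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    y = _check_labels(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels length mismatch")

    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    if method == "delong":
        auc, var = _delong_variance(s, y)
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    elif method == "bootstrap":
        auc = _auc_mann_whitney(s, y)
        rng = np.random.default_rng(seed)
        idx_pos, idx_neg = np.flatnonzero(y), np.flatnonzero(~y)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(idx_pos, len(idx_pos))
            bn = rng.choice(idx_neg, len(idx_neg))
            bi = np.concatenate([bp, bn])
            reps[b] = _auc_mann_whitney(s[bi], y[bi])
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ROCResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi), curve=curve,
        method=method, n_pos=int(y.sum()), n_neg=int((~y).sum()),
    )


def compare_auc_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> tuple[float, float]:
    """DeLong paired test for two markers measured on the same patients.

    Returns ``(delta_auc, p_value)`` with ``delta_auc = auc_b - auc_a``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _check_labels(labels)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("scores_a, scores_b and labels must have equal length")

    v10_a, v01_a = _delong_components(a, y)
    v10_b, v01_b = _delong_components(b, y)
    auc_a, auc_b = float(np.mean(v10_a)), float(np.mean(v10_b))
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_b - auc_a
    if var_delta <= 0:
        # Identical (or rank-identical) markers: no evidence of a difference.
        return delta, 1.0
    z = delta / np.sqrt(var_delta)
    p = 2 * stats.norm.sf(abs(z))
    return delta, float(p)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression summary.

    ``terms`` are coefficients on the log-odds scale (including ``const``);
    ``table`` reports odds ratios with Wald 95% intervals and p-values per
    non-intercept term; ``predicted`` holds in-sample event probabilities.
    """

    terms: pd.Series
    table: pd.DataFrame  # columns: odds_ratio, ci_low, ci_high, p_value
    conf_int: pd.DataFrame  # Wald intervals on the coefficient scale, incl. const
    n: int
    predicted: np.ndarray
    converged: bool
    outcome: str = "urgent"

    @property
    def odds_ratios(self) -> pd.Series:
        return self.table["odds_ratio"]

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = sm.add_constant(X[self.terms.index.drop("const")], has_constant="add")
        eta = design.to_numpy() @ self.terms.reindex(design.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "converged": self.converged,
            "coefficients": self.terms.to_dict(),
            "odds_ratios": self.table.to_dict(orient="index"),
        }


_PREDICTOR_COLUMNS = {
    "fit": "fit_value",
    "fit_value": "fit_value",
    "haemoglobin": "haemoglobin",
    "age": "age",
    "sex": "sex",
}


def _design_matrix(cohort: CohortTable, predictors: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for term in predictors:
        key = _PREDICTOR_COLUMNS.get(term, term)
        if key == "sex":
            cols["sex_male"] = (cohort.frame["sex"] == "male").astype(float)
        elif key in cohort.frame.columns:
            cols[key] = cohort.frame[key].astype(float)
        else:
            raise KeyError(f"unknown predictor {term!r}")
    return pd.DataFrame(cols)


def fit_logistic(
    cohort: CohortTable,
    predictors: Sequence[str] = ("fit_value",),
    outcome: str = "urgent",
    alpha: float = 0.05,
) -> LogisticFit:
    """Fit ``outcome ~ predictors`` by maximum likelihood.

    Predictor names map to cohort columns (``fit``/``fit_value``, ``age``,
    ``haemoglobin``, ``sex`` — sex enters as an indicator for male).  Raises
    :class:`SeparationError` on complete separation and ``ValueError`` for a
    zero-variance predictor or single-class outcome.
    """
    y = cohort.outcome(outcome).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"outcome {outcome!r} has a single class; logistic model undefined")
    X = _design_matrix(cohort, predictors)
    for name, col in X.items():
        if np.ptp(col.to_numpy()) == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("more model terms than observations")

    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            if "separation" in str(exc).lower():
                raise SeparationError(f"complete separation detected: {exc}") from exc
            raise
    sep = any("separation" in str(w.message).lower() for w in caught)
    if sep or np.abs(res.params.drop("const", errors="ignore")).max() > 50:
        raise SeparationError(
            "complete or quasi-complete separation: coefficient estimates diverge"
        )

    params = res.params
    conf = res.conf_int(alpha)
    rows = {}
    for term in params.index:
        if term == "const":
            continue
        rows[term] = {
            "odds_ratio": float(np.exp(params[term])),
            "ci_low": float(np.exp(conf.loc[term, 0])),
            "ci_high": float(np.exp(conf.loc[term, 1])),
            "p_value": float(res.pvalues[term]),
        }
    conf.columns = ["ci_low", "ci_high"]
    return LogisticFit(
        terms=params,
        table=pd.DataFrame.from_dict(rows, orient="index"),
        conf_int=conf,
        n=int(res.nobs),
        predicted=np.asarray(res.predict(design)),
        converged=bool(res.mle_retvals.get("converged", True)),
        outcome=outcome,
    )


def adjusted_roc(
    cohort: CohortTable,
    outcome: str = "urgent",
    predictors: Sequence[str] = ("fit_value", "haemoglobin", "age", "sex"),
) -> ROCResult:
    """ROC of the multivariable model's in-sample predicted probabilities.

    This is *apparent* (non-cross-validated) discrimination, flagged as such
    in the result.  With FIT as the only predictor it coincides with the
    unadjusted ROC because AUC is invariant to monotone score transforms.
    """
    fit = fit_logistic(cohort, predictors=predictors, outcome=outcome)
    res = roc_with_ci(fit.predicted, cohort.outcome(outcome))
    return ROCResult(
        auc=res.auc, ci_low=res.ci_low, ci_high=res.ci_high, curve=res.curve,
        method=res.method, n_pos=res.n_pos, n_neg=res.n_neg, apparent=True,
    )
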