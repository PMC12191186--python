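"""Decision-curve analysis and the adapted monetary cost–benefit analysis.

Decision-curve analysis (DCA) evaluates a triage rule over the full range of
threshold probabilities p_t: a patient is classified high-risk (sent straight
to colonoscopy) when their predicted conversion probability is at least p_t,
and the net benefit of that policy is

    NB(p_t) = TP/n − (FP/n) · p_t / (1 − p_t)

in units of true positives per patient, compared against the treat-all and
treat-none reference policies.  The risk model is the univariate logistic
model of the urgent label on the continuous FIT value, so each p_t maps back
to a FIT threshold through the model's inverse link.

The monetary analysis replaces the p_t/(1−p_t) exchange rate with explicit
per-outcome values in GBP: true positives skip an unnecessary capsule, true
negatives avoid a colonoscopy, false positives pay the colonoscopy/capsule
price difference, and false negatives pay for the capsule that converts to
colonoscopy anyway.  The capsule is priced at 83% of colonoscopy by default
(a published 17% cost saving); absolute prices are deliberately user-supplied
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CohortTable
from .models import LogisticFit, fit_logistic

__all__ = [
    "DCACurve",
    "CostModel",
    "MonetaryCurve",
    "OptimalBand",
    "dca_curve",
    "prob_to_fit",
    "monetary_curve",
    "steepest_declines",
    "optimal_band",
]


@dataclass(frozen=True)
class DCACurve:
    """Net benefit of the FIT-based risk model over threshold probabilities."""

    thresholds: np.ndarray  # p_t grid, 0..1
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray  # NaN at p_t = 1 (exchange rate diverges)
    net_benefit_none: np.ndarray  # identically zero
    fit_at_threshold: np.ndarray  # µg/g via the model inverse; NaN at p_t ∈ {0, 1}
    extrapolated: np.ndarray  # fit_at_threshold outside the observed FIT range
    prevalence: float
    model: LogisticFit | None
    best_threshold: float  # p_t maximising model net benefit
    best_fit: float  # its FIT image (µg/g; NaN if unmapped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_t": self.thresholds,
                "net_benefit_model": self.net_benefit_model,
                "net_benefit_all": self.net_benefit_all,
                "net_benefit_none": self.net_benefit_none,
                "fit_at_threshold": self.fit_at_threshold,
                "extrapolated": self.extrapolated,
            }
        )


def dca_curve(
    cohort: CohortTable,
    outcome: str = "urgent",
    grid_step: float = 0.01,
    probabilities: np.ndarray | None = None,
) -> DCACurve:
    """Decision curve for the univariate FIT risk model.

    At each p_t on the 0–1 grid (default step 0.01) patients with predicted
    probability ≥ p_t are classified high-risk; net benefit is
    TP/n − (FP/n)·p_t/(1−p_t).  p_t = 1 is handled as the classify-none limit
    (net benefit 0); the treat-all curve equals the prevalence at p_t = 0.

    ``probabilities`` substitutes externally supplied risk estimates for the
    fitted model's (e.g. for a risk model whose probabilities separate the
    classes completely, where a logistic fit is undefined); the probability↔FIT
    mapping is then unavailable.
    """
    y = cohort.outcome(outcome)
    if y.all() or not y.any():
        raise ValueError(f"outcome {outcome!r} has a single class; DCA undefined")
    if probabilities is None:
        model = fit_logistic(cohort, predictors=("fit_value",), outcome=outcome)
        probs = model.predicted
    else:
        model = None
        probs = np.asarray(probabilities, dtype=float)
        if probs.shape != y.shape or np.any((probs < 0) | (probs > 1)):
            raise ValueError("probabilities must be per-patient values in [0, 1]")
    n = len(y)
    prevalence = float(y.mean())

    n_steps = int(round(1.0 / grid_step))
    pt = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)
    nb_model = np.empty_like(pt)
    nb_all = np.empty_like(pt)
    for i, p in enumerate(pt):
        if p >= 1.0:
            nb_model[i] = 0.0  # classify-none limit
            nb_all[i] = np.nan
            continue
        w = p / (1.0 - p)
        high = probs >= p
        tp = np.count_nonzero(high & y)
        fp = np.count_nonzero(high & ~y)
        nb_model[i] = tp / n - (fp / n) * w
        nb_all[i] = prevalence - (1.0 - prevalence) * w
    nb_none = np.zeros_like(pt)

    fit_at = np.full_like(pt, np.nan)
    interior = (pt > 0) & (pt < 1)
    if model is not None:
        beta0 = float(model.terms["const"])
        beta1 = float(model.terms["fit_value"])
        if beta1 > 0:
            fit_at[interior] = (logit(pt[interior]) - beta0) / beta1
    fmin, fmax = cohort.fit_values.min(), cohort.fit_values.max()
    extrapolated = np.where(
        np.isnan(fit_at), False, (fit_at < fmin) | (fit_at > fmax)
    )

    # "Best" threshold: argmax of model net benefit over the region where the
    # model strictly beats both reference policies (at p_t = 0 the model ties
    # with treat-all by construction, which is not a usable operating point);
    # falls back to the global argmax when no such region exists.
    above = (nb_model > 0) & (np.isnan(nb_all) | (nb_model > nb_all))
    if above.any():
        cand = np.where(above, nb_model, -np.inf)
        best_idx = int(np.argmax(cand))
    else:
        best_idx = int(np.nanargmax(nb_model))
    return DCACurve(
        thresholds=pt,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=nb_none,
        fit_at_threshold=fit_at,
        extrapolated=extrapolated,
        prevalence=prevalence,
        model=model,
        best_threshold=float(pt[best_idx]),
        best_fit=float(fit_at[best_idx]),
    )


def prob_to_fit(fit_model: LogisticFit, p_t: float) -> float:
    """Invert the FIT risk model: the FIT value whose predicted probability is p_t.

    Requires a univariate model with a positive FIT slope; FIT = (logit(p_t) −
    β0)/β1.  Callers should treat values outside the observed FIT range as
    extrapolated (see :class:`DCACurve`).
    """
    if not 0 < p_t < 1:
        raise ValueError(f"p_t must lie strictly between 0 and 1, got {p_t}")
    try:
        beta0 = float(fit_model.terms["const"])
        beta1 = float(fit_model.terms["fit_value"])
    except KeyError as exc:
        raise ValueError("model must contain a single FIT term plus intercept") from exc
    if beta1 <= 0:
        raise ValueError(
            f"FIT slope must be positive for a monotone threshold mapping, got {beta1}"
        )
    return float((logit(p_t) - beta0) / beta1)


@dataclass(frozen=True)
class CostModel:
    """Per-outcome monetary values (GBP) for the triage policy.

    ``cost_cce`` defaults to 83% of ``cost_colonoscopy``.  Outcome values
    default to the triage narrative: a true positive saves the unnecessary
    capsule (``cost_cce``), a true negative avoids a colonoscopy
    (``cost_colonoscopy``), a false positive loses the colonoscopy/capsule
    price difference, and a false negative loses the capsule that converts
    anyway (incremental reading; the absolute both-procedures reading is
    ``fn_absolute=True``).
    """

    cost_colonoscopy: float = 1.0
    cost_cce: float | None = None
    value_tp: float | None = None
    value_tn: float | None = None
    loss_fp: float | None = None
    loss_fn: float | None = None
    fn_absolute: bool = False

    def __post_init__(self) -> None:
        if self.cost_colonoscopy < 0:
            raise ValueError("cost_colonoscopy must be non-negative")
        if self.cost_cce is None:
            object.__setattr__(self, "cost_cce", 0.83 * self.cost_colonoscopy)
        if self.value_tp is None:
            object.__setattr__(self, "value_tp", self.cost_cce)
        if self.value_tn is None:
            object.__setattr__(self, "value_tn", self.cost_colonoscopy)
        if self.loss_fp is None:
            object.__setattr__(self, "loss_fp", self.cost_colonoscopy - self.cost_cce)
        if self.loss_fn is None:
            fn = self.cost_cce + self.cost_colonoscopy if self.fn_absolute else self.cost_cce
            object.__setattr__(self, "loss_fn", fn)
        for name in ("cost_cce", "value_tp", "value_tn", "loss_fp", "loss_fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "CostModel":
        return cls(cost_colonoscopy=0.0, cost_cce=0.0, value_tp=0.0,
                   value_tn=0.0, loss_fp=0.0, loss_fn=0.0)

    def scaled(self, k: float) -> "CostModel":
        return CostModel(
            cost_colonoscopy=k * self.cost_colonoscopy, cost_cce=k * self.cost_cce,
            value_tp=k * self.value_tp, value_tn=k * self.value_tn,
            loss_fp=k * self.loss_fp, loss_fn=k * self.loss_fn,
        )


@dataclass(frozen=True)
class MonetaryCurve:
    """Net monetary benefit per patient across FIT triage thresholds."""

    fit_grid: np.ndarray  # µg/g
    net_benefit_gbp: np.ndarray  # per patient
    counts: pd.DataFrame  # tp, fp, tn, fn per threshold
    costs: CostModel
    n: int

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "threshold", self.fit_grid)
        out["net_benefit_gbp"] = self.net_benefit_gbp
        return out


def monetary_curve(
    cohort: CohortTable,
    costs: CostModel,
    fit_grid: Sequence[float],
) -> MonetaryCurve:
    """Net monetary benefit per patient at each FIT threshold.

    At threshold t a patient is triaged straight to colonoscopy (predicted
    positive) iff FIT > t, otherwise to capsule first.  Confusion cells are
    counted against the urgent label and valued per the :class:`CostModel`:

        NB(t) = (value_tp·TP + value_tn·TN − loss_fp·FP − loss_fn·FN) / n
    """
    grid = np.asarray(fit_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("fit_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("fit_grid must be ascending")
    fit = cohort.fit_values
    y = cohort.urgent
    n = cohort.n

    rows = []
    nb = np.empty(grid.size)
    for i, t in enumerate(grid):
        positive = fit > t
        tp = int(np.count_nonzero(positive & y))
        fp = int(np.count_nonzero(positive & ~y))
        fn = int(np.count_nonzero(~positive & y))
        tn = int(np.count_nonzero(~positive & ~y))
        nb[i] = (
            costs.value_tp * tp + costs.value_tn * tn
            - costs.loss_fp * fp - costs.loss_fn * fn
        ) / n
        rows.append({"tp": tp, "fp": fp, "tn": tn, "fn": fn})
    return MonetaryCurve(
        fit_grid=grid, net_benefit_gbp=nb, counts=pd.DataFrame(rows),
        costs=costs, n=n,
    )


def steepest_declines(curve: MonetaryCurve, k: int = 5) -> list[tuple[float, float]]:
    """The k thresholds with the largest one-step drop in net benefit.

    Returns ``[(threshold, drop), ...]`` sorted by drop descending, ties
    broken toward the lower threshold; only strictly positive drops count, so
    a monotone non-decreasing curve yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if curve.fit_grid.size < 2:
        raise ValueError("curve needs at least 2 grid points")
    drops = curve.net_benefit_gbp[:-1] - curve.net_benefit_gbp[1:]
    candidates = [
        (float(curve.fit_grid[i + 1]), float(d))
        for i, d in enumerate(drops)
        if d > 0
    ]
    candidates.sort(key=lambda td: (-td[1], td[0]))
    return candidates[:k]


@dataclass(frozen=True)
class OptimalBand:
    """Maximal p_t interval where the model beats both reference policies."""

    p_low: float
    p_high: float
    fit_low: float  # µg/g image of p_low (NaN if unmapped)
    fit_high: float
    argmax_p: float
    argmax_fit: float
    argmax_net_benefit: float


def optimal_band(dca: DCACurve) -> OptimalBand | None:
    """Locate the threshold-probability band of positive clinical utility.

    The maximal contiguous run of grid points where the model's net benefit
    strictly exceeds both treat-all and treat-none.  Returns ``None`` when no
    grid point qualifies (a valid outcome: the model is never useful).
    """
    nb_m, nb_a = dca.net_benefit_model, dca.net_benefit_all
    above = (nb_m > dca.net_benefit_none) & (np.isnan(nb_a) | (nb_m > nb_a))
    if not above.any():
        return None
    # Longest contiguous run (first on ties).
    best_start = best_len = 0
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    lo, hi = best_start, best_start + best_len - 1
    seg = slice(lo, hi + 1)
    arg = lo + int(np.nanargmax(nb_m[seg]))
    return OptimalBand(
        p_low=float(dca.thresholds[lo]),
        p_high=float(dca.thresholds[hi]),
        fit_low=float(dca.fit_at_threshold[lo]),
        fit_high=float(dca.fit_at_threshold[hi]),
        argmax_p=float(dca.thresholds[arg]),
        argmax_fit=float(dca.fit_at_threshold[arg]),
        argmax_net_benefit=float(nb_m[arg]),
    )
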