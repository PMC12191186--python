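"""Threshold-based analysis: CUSUM cumulative-count scan and significance scan.

The CUSUM scan walks an ascending grid of FIT thresholds in exact 0.1 µg/g
steps (stored as integers in deci-µg/g, so there is no floating-point
accumulation) and counts, at each threshold t, the urgent conversions among
patients with FIT ≤ t.  A *jump point* is a grid step where that cumulative
count rises by at least ``min_jump`` cases — in practice these mark assay
detection limits (7, 10, 400) and genuine risk inflections.  The conversion
rate at t is the proportion of urgent cases among the patients who would be
triaged to capsule at that threshold (FIT ≤ t); the whole-cohort denominator
is available behind a flag.

The incremental significance scan refines the threshold inside a window:
patients with FIT at or below ``g1_max`` form a low-FIT reference group, and
for each candidate threshold t the patients with g1_max < FIT ≤ t are compared
against it by logistic regression on group membership, giving an odds ratio,
Wald interval and p-value per t.  The *first sustained* threshold is the
smallest t that is significant at t and at every larger evaluable t in the
scan range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .models import SeparationError, fit_logistic

__all__ = [
    "CusumScan",
    "SignificanceScan",
    "cusum_scan",
    "conversion_rate_at",
    "incremental_significance_scan",
]


@dataclass(frozen=True)
class CusumScan:
    """Cumulative urgent counts over an exact deci-µg/g threshold grid."""

    grid_deci: np.ndarray  # int64, deci-µg/g; step is exactly one unit times `unit`
    unit: int  # grid step in deci-µg/g (1 ⇔ 0.1 µg/g)
    cum_urgent: np.ndarray
    cum_total: np.ndarray
    jump_points: np.ndarray  # µg/g
    jump_sizes: np.ndarray  # urgent-count increment at each jump point
    min_jump: int
    denominator: str  # "triaged" or "cohort"
    n: int

    @property
    def thresholds(self) -> np.ndarray:
        """Grid in µg/g."""
        return self.grid_deci / 10.0

    @property
    def conversion_rate(self) -> np.ndarray:
        if self.denominator == "cohort":
            return self.cum_urgent / self.n
        return np.divide(
            self.cum_urgent,
            self.cum_total,
            out=np.zeros_like(self.cum_urgent, dtype=float),
            where=self.cum_total > 0,
        )

    @property
    def rate_diffs(self) -> np.ndarray:
        """Absolute conversion-rate differences between consecutive jump points."""
        if len(self.jump_points) < 2:
            return np.array([])
        rates = np.array([conversion_rate_at(self, t) for t in self.jump_points])
        return np.abs(np.diff(rates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "cum_urgent": self.cum_urgent,
                "cum_total": self.cum_total,
                "conversion_rate": self.conversion_rate,
            }
        )

    def summary(self) -> dict:
        return {
            "n": self.n,
            "min_jump": self.min_jump,
            "denominator": self.denominator,
            "jump_points": [float(t) for t in self.jump_points],
            "jump_sizes": [int(s) for s in self.jump_sizes],
            "rate_diffs": [float(d) for d in self.rate_diffs],
        }


def _to_deci(values: np.ndarray) -> np.ndarray:
    return np.rint(np.asarray(values, dtype=float) * 10).astype(np.int64)


def cusum_scan(
    cohort: CohortTable,
    step: float = 0.1,
    min_jump: int = 5,
    denominator: Literal["triaged", "cohort"] = "triaged",
) -> CusumScan:
    """Scan cumulative urgent counts over incrementally increasing FIT thresholds.

    The grid runs from ``floor(min FIT)`` to the maximum FIT value inclusive
    in exact integer deci-µg/g arithmetic.  A jump point is a threshold whose
    cumulative urgent count exceeds the immediately previous grid point's by
    at least ``min_jump`` cases.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if min_jump < 1:
        raise ValueError("min_jump must be at least 1")
    unit = int(round(step * 10))
    if unit < 1 or abs(unit - step * 10) > 1e-9:
        raise ValueError("step must be a positive multiple of 0.1 µg/g")

    fit_deci = _to_deci(cohort.fit_values)
    urgent = cohort.urgent
    start = int(np.floor(fit_deci.min() / 10.0)) * 10
    stop = int(fit_deci.max())
    n_steps = max(0, -(-(stop - start) // unit))  # ceil division; grid reaches max
    grid = start + unit * np.arange(n_steps + 1, dtype=np.int64)

    all_sorted = np.sort(fit_deci)
    urg_sorted = np.sort(fit_deci[urgent])
    cum_total = np.searchsorted(all_sorted, grid, side="right")
    cum_urgent = np.searchsorted(urg_sorted, grid, side="right")

    # Increment vs the immediately previous grid point; the point before the
    # grid start counts patients with FIT <= start - unit.
    prev_urgent = np.concatenate(
        [[np.searchsorted(urg_sorted, grid[0] - unit, side="right")], cum_urgent[:-1]]
    )
    increments = cum_urgent - prev_urgent
    jump_mask = increments >= min_jump
    return CusumScan(
        grid_deci=grid,
        unit=unit,
        cum_urgent=cum_urgent.astype(np.int64),
        cum_total=cum_total.astype(np.int64),
        jump_points=grid[jump_mask] / 10.0,
        jump_sizes=increments[jump_mask].astype(np.int64),
        min_jump=min_jump,
        denominator=denominator,
        n=cohort.n,
    )


def conversion_rate_at(scan: CusumScan, t: float) -> float:
    """Conversion rate at a grid threshold t (µg/g); errors if t is off-grid."""
    t_deci = int(np.rint(t * 10))
    idx = np.searchsorted(scan.grid_deci, t_deci)
    if idx >= len(scan.grid_deci) or scan.grid_deci[idx] != t_deci:
        near = scan.grid_deci[min(idx, len(scan.grid_deci) - 1)] / 10.0
        raise ValueError(f"threshold {t} µg/g is not on the scan grid (nearest grid point: {near})")
    return float(scan.conversion_rate[idx])


@dataclass(frozen=True)
class SignificanceScan:
    """Per-threshold comparison of rising-FIT patients against a low-FIT group."""

    rows: pd.DataFrame  # t, n1, n2, events1, events2, odds_ratio, ci_low, ci_high, p_value, flagged
    g1_max: float
    scan_lo: float
    scan_hi: float
    alpha: float
    group2_mode: str  # "cumulative": Group2 = (g1_max, t];  "upper": Group2 = [t, scan_hi]
    first_sustained: float | None

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def incremental_significance_scan(
    cohort: CohortTable,
    g1_max: float = 10.0,
    scan_lo: float = 11.0,
    scan_hi: float = 29.0,
    step: float = 1.0,
    alpha: float = 0.05,
    group2_mode: Literal["cumulative", "upper"] = "cumulative",
) -> SignificanceScan:
    """Locate the lowest threshold with a persistently significant urgent excess.

    Group 1 (reference) is FIT ≤ ``g1_max``.  For each t on the grid, Group 2
    is ``(g1_max, t]`` (``"cumulative"``, default) or ``[t, scan_hi]``
    (``"upper"``).  Each comparison is a logistic regression of the urgent
    label on group membership; rows with an empty group or a zero cell are
    flagged as unevaluable rather than dropped, and are excluded from the
    sustained-run logic.
    """
    fit = cohort.fit_values
    urgent = cohort.urgent
    g1 = fit <= g1_max
    if not g1.any():
        raise ValueError(f"Group 1 (FIT <= {g1_max}) is empty")

    grid = np.round(np.arange(scan_lo, scan_hi + step / 2, step), 10)
    rows = []
    for t in grid:
        if group2_mode == "cumulative":
            g2 = (fit > g1_max) & (fit <= t)
        else:
            g2 = (fit >= t) & (fit <= scan_hi)
        n1, n2 = int(g1.sum()), int(g2.sum())
        e1, e2 = int(urgent[g1].sum()), int(urgent[g2].sum())
        row = {
            "t": float(t), "n1": n1, "n2": n2, "events1": e1, "events2": e2,
            "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p_value": np.nan, "flagged": True,
        }
        zero_cell = (
            n2 == 0 or e1 == 0 or e2 == 0 or e1 == n1 or e2 == n2
        )
        if not zero_cell:
            mask = g1 | g2
            sub = CohortTable(
                cohort.frame.loc[mask].assign(group2=g2[mask].astype(float)),
                provenance="significance-scan subset",
                criteria=cohort.criteria,
            )
            try:
                fit_res = fit_logistic(sub, predictors=("group2",), outcome="urgent")
                tab = fit_res.table.loc["group2"]
                row.update(
                    odds_ratio=tab["odds_ratio"], ci_low=tab["ci_low"],
                    ci_high=tab["ci_high"], p_value=tab["p_value"], flagged=False,
                )
            except (SeparationError, ValueError):
                pass  # stays flagged
        rows.append(row)

    frame = pd.DataFrame(rows)
    valid = frame[~frame["flagged"]]
    first_sustained: float | None = None
    for t in valid["t"]:
        tail = valid[valid["t"] >= t]
        if (tail["p_value"] < alpha).all():
            first_sustained = float(t)
            break
    return SignificanceScan(
        rows=frame, g1_max=g1_max, scan_lo=scan_lo, scan_hi=scan_hi,
        alpha=alpha, group2_mode=group2_mode, first_sustained=first_sustained,
    )
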