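"""Study orchestration: power calculation, descriptives, and the full pipeline.

``run_full_analysis`` sequences the whole study on a loaded or simulated
cohort — descriptive summary, ROC accuracy for cancer / polypoid lesions /
urgent conversion, the CUSUM threshold scan with jump points, the incremental
significance scan, decision-curve analysis, and the monetary cost–benefit
curve — writing CSV tables, JSON summaries and (optionally) figures to an
output directory with a machine-readable index.  A run is reproducible from
its configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import CohortTable, ConversionCriteria, load_cohort
from .decision import (
    CostModel,
    dca_curve,
    monetary_curve,
    optimal_band,
    steepest_declines,
)
from .models import adjusted_roc, compare_auc_paired, fit_logistic, roc_with_ci
from .simulate import SyntheticParams, generate_cohort
from .thresholds import cusum_scan, incremental_significance_scan

__all__ = [
    "PowerSpec",
    "SampleSizeResult",
    "RunConfig",
    "StageError",
    "sample_size_two_sample_t",
    "summarise_cohort",
    "proportion_pct",
    "run_full_analysis",
]

log = logging.getLogger("fittriage")


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test design: detect a mean FIT difference ``delta`` (µg/g)
    against common SD ``sd`` at two-sided ``alpha`` with target ``power``."""

    delta: float = 20.0
    sd: float = 117.0
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.sd <= 0:
            raise ValueError("delta and sd must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")

    @property
    def cohen_d(self) -> float:
        return self.delta / self.sd


@dataclass(frozen=True)
class SampleSizeResult:
    total: int  # ceiling of twice the continuous per-group solution
    per_group_continuous: float
    per_group_normal_approx: float  # large-sample z-formula, for transparency
    spec: PowerSpec

    @property
    def total_per_group_rounding(self) -> int:
        """Alternative rounding: per-group ceiling first, then doubled.

        ``total`` rounds the doubled continuous solution (which can yield an
        odd total); this convention rounds each group up instead.
        """
        return 2 * math.ceil(self.per_group_continuous)


def _t_power(n_per_group: float, d: float, alpha: float) -> float:
    df = 2.0 * (n_per_group - 1.0)
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_two_sample_t(spec: PowerSpec) -> SampleSizeResult:
    """Solve the two-sided two-sample t-test sample size via noncentral-t power.

    Returns the total N = ceil(2 · n_per_group) for the continuous per-group
    solution; at the defaults (d = 20/117, α = 0.05, power 0.90) this is 1441.
    The normal-approximation per-group value 2(z_{1−α/2}+z_{power})²/d² is
    reported alongside.
    """
    d = spec.cohen_d
    if d == 0:
        raise ValueError("zero effect size: required sample size is infinite")
    target = spec.power
    # stats.nct loses accuracy at extreme df, so bracket by doubling.
    hi = 4.0
    while _t_power(hi, d, spec.alpha) < target:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("sample-size solve failed to bracket")
    n = optimize.brentq(lambda m: _t_power(m, d, spec.alpha) - target, 2.0, hi, xtol=1e-8)
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    normal_n = 2.0 * (z_a + z_b) ** 2 / d**2
    return SampleSizeResult(
        total=int(math.ceil(2.0 * n)),
        per_group_continuous=float(n),
        per_group_normal_approx=float(normal_n),
        spec=spec,
    )


def proportion_pct(count: int, n: int) -> float:
    """Percentage to one decimal place, Table-style (211/1531 -> 13.8)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / n, 1)


def summarise_cohort(cohort: CohortTable) -> dict[str, Any]:
    """Descriptive summary: counts with 1-dp percentages for categorical
    fields, mean ± SD and median for FIT, age and haemoglobin."""
    f = cohort.frame
    n = len(f)

    def cont(col: str) -> dict[str, Any]:
        x = f[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if n > 1 else None
        return {
            "mean": float(np.mean(x)),
            "sd": sd,
            "sd_defined": n > 1,
            "median": float(np.median(x)),
        }

    def cat(mask: pd.Series | np.ndarray) -> dict[str, Any]:
        c = int(np.count_nonzero(mask))
        return {"count": c, "pct": proportion_pct(c, n)}

    advanced = f["max_polyp_size"] >= cohort.criteria.size_threshold
    return {
        "n": n,
        "fit": cont("fit_value"),
        "age": cont("age"),
        "haemoglobin": cont("haemoglobin"),
        "sex": {
            "male": cat(f["sex"] == "male"),
            "female": cat(f["sex"] == "female"),
        },
        "findings": {
            "crc": cat(f["crc"]),
            "any_polyp": cat(f["polyp_count"] > 0),
            "advanced_polyp": cat(advanced),
            "urgent": cat(f["urgent"]),
        },
        "bowel_prep": {
            level: cat(f["bowel_prep"] == level)
            for level in ("adequate", "poor", "missing")
        },
        "fit_censoring": {
            level: cat(f["fit_censoring"] == level)
            for level in ("exact", "below_lower_limit", "above_upper_limit")
        },
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run.

    ``input_csv`` takes precedence over ``synthetic``; exactly one must be
    set.  ``seed`` overrides the synthetic generator's seed so a single
    integer drives the whole run.
    """

    input_csv: str | None = None
    synthetic: SyntheticParams | None = None
    criteria: ConversionCriteria = field(default_factory=ConversionCriteria)
    lower_limits: tuple[float, ...] = (7.0, 10.0)
    upper_limit: float = 400.0
    scan_step: float = 0.1
    min_jump: int = 5
    g1_max: float = 10.0
    scan_lo: float = 11.0
    scan_hi: float = 29.0
    scan_alpha: float = 0.05
    costs: CostModel = field(default_factory=CostModel)
    monetary_grid_lo: float = 1.0
    monetary_grid_hi: float = 400.0
    monetary_grid_step: float = 1.0
    dca_grid_step: float = 0.01
    outdir: str = "results"
    seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                v = dataclasses.asdict(v)
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, (frozenset, set)):
                return sorted(v)
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            return v

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("synthetic"):
            raw["synthetic"] = SyntheticParams(**raw["synthetic"])
        if raw.get("criteria"):
            c = dict(raw["criteria"])
            c["extra_urgent_findings"] = frozenset(c.get("extra_urgent_findings", ()))
            raw["criteria"] = ConversionCriteria(**c)
        if raw.get("costs"):
            raw["costs"] = CostModel(**raw["costs"])
        if raw.get("lower_limits"):
            raw["lower_limits"] = tuple(raw["lower_limits"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def _json_default(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON-serialisable: {type(v)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the whole study and write its outputs.

    Returns the JSON index (also written to ``<outdir>/index.json``): file
    list with SHA-256 hashes for CSV/JSON artefacts, per-stage headline
    numbers, the configuration, and any stages skipped for lack of events.
    Raises :class:`StageError` on the first failing stage, after writing a
    partial manifest.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index: dict[str, Any] = {
        "config": config.to_dict(),
        "files": {},
        "results": {},
        "skipped": {},
    }
    files: dict[str, str] = index["files"]

    def emit_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        files[name] = _sha256(path)

    def emit_json(name: str, obj: Any) -> None:
        path = outdir / name
        _write_json(path, obj)
        files[name] = _sha256(path)

    stage = "load"
    try:
        if config.input_csv is not None:
            cohort = load_cohort(
                config.input_csv, criteria=config.criteria,
                lower_limits=config.lower_limits, upper_limit=config.upper_limit,
            )
        elif config.synthetic is not None:
            params = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = generate_cohort(params, criteria=config.criteria)
        else:
            raise ValueError("config must set input_csv or synthetic")
        log.info("stage %s: cohort of %d patients (%s)", stage, cohort.n, cohort.provenance)
        path = outdir / "cohort.csv"
        cohort.to_csv(path)
        files["cohort.csv"] = _sha256(path)

        stage = "summary"
        summary = summarise_cohort(cohort)
        emit_json("summary.json", summary)
        index["results"]["n"] = cohort.n
        index["results"]["urgent_prevalence"] = summary["findings"]["urgent"]["pct"]

        stage = "roc"
        roc_out: dict[str, Any] = {}
        for outcome in ("crc", "polypoid", "urgent"):
            y = cohort.outcome(outcome)
            if y.all() or not y.any():
                index["skipped"][f"roc_{outcome}"] = "insufficient events: single-class outcome"
                log.warning("stage roc: skipping %s (single-class outcome)", outcome)
                continue
            res = roc_with_ci(cohort.fit_values, y)
            roc_out[outcome] = res.to_dict()
            emit_csv(f"roc_curve_{outcome}.csv", res.curve)
        if "urgent" in roc_out:
            adj = adjusted_roc(cohort, outcome="urgent")
            mv = fit_logistic(
                cohort, predictors=("fit_value", "haemoglobin", "age", "sex"),
                outcome="urgent",
            )
            delta, p = compare_auc_paired(cohort.fit_values, mv.predicted, cohort.urgent)
            roc_out["urgent_adjusted"] = adj.to_dict()
            roc_out["urgent_adjusted_vs_fit_only"] = {"delta_auc": delta, "p_value": p}
            emit_json("logistic_multivariable.json", mv.to_dict())
        emit_json("roc.json", roc_out)
        index["results"]["roc"] = {
            k: v["auc"] for k, v in roc_out.items() if isinstance(v, dict) and "auc" in v
        }

        stage = "cusum"
        scan = cusum_scan(cohort, step=config.scan_step, min_jump=config.min_jump)
        emit_csv("cusum_scan.csv", scan.to_frame())
        emit_json("cusum_jumps.json", scan.summary())
        index["results"]["jump_points"] = [float(t) for t in scan.jump_points]

        stage = "significance_scan"
        sig = incremental_significance_scan(
            cohort, g1_max=config.g1_max, scan_lo=config.scan_lo,
            scan_hi=config.scan_hi, alpha=config.scan_alpha,
        )
        emit_csv("significance_scan.csv", sig.rows)
        index["results"]["first_sustained_threshold"] = sig.first_sustained

        stage = "dca"
        dca = dca_curve(cohort, grid_step=config.dca_grid_step)
        emit_csv("dca_curve.csv", dca.to_frame())
        band = optimal_band(dca)
        dca_summary = {
            "prevalence": dca.prevalence,
            "best_threshold_probability": dca.best_threshold,
            "best_fit_ug_g": dca.best_fit,
            "optimal_band": dataclasses.asdict(band) if band else None,
        }
        emit_json("dca_summary.json", dca_summary)
        index["results"]["dca"] = dca_summary

        stage = "monetary"
        grid = np.round(
            np.arange(
                config.monetary_grid_lo,
                config.monetary_grid_hi + config.monetary_grid_step / 2,
                config.monetary_grid_step,
            ),
            10,
        )
        money = monetary_curve(cohort, config.costs, grid)
        declines = steepest_declines(money, k=5)
        emit_csv("monetary_curve.csv", money.to_frame())
        emit_json(
            "monetary_summary.json",
            {
                "best_threshold": float(money.fit_grid[int(np.argmax(money.net_benefit_gbp))]),
                "best_net_benefit_gbp": float(money.net_benefit_gbp.max()),
                "steepest_declines": [
                    {"threshold": t, "drop_gbp": d} for t, d in declines
                ],
            },
        )
        index["results"]["monetary_best_threshold"] = float(
            money.fit_grid[int(np.argmax(money.net_benefit_gbp))]
        )

        if config.make_plots:
            stage = "plots"
            plot_files = _render_plots(outdir, scan, dca, money)
            index["plots"] = plot_files  # not hashed: images are presentation only
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        _write_json(outdir / "partial_manifest.json", {"failed_stage": stage, "files": files})
        raise StageError(stage, {"failed_stage": stage, "files": files}, exc) from exc

    _write_json(outdir / "index.json", index)
    return index


def _render_plots(outdir: Path, scan, dca, money) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    axes[0].step(scan.thresholds, scan.cum_urgent, where="post")
    for t in scan.jump_points:
        axes[0].axvline(t, color="red", ls="--", lw=0.6)
    axes[0].set_xscale("symlog")
    axes[0].set_xlabel("FIT threshold (µg/g)")
    axes[0].set_ylabel("Cumulative urgent conversions")
    axes[0].set_title(f"CUSUM scan; jump points: {', '.join(f'{t:g}' for t in scan.jump_points)}")
    axes[1].step(scan.thresholds, 100 * scan.conversion_rate, where="post")
    axes[1].set_xscale("symlog")
    axes[1].set_xlabel("FIT threshold (µg/g)")
    axes[1].set_ylabel("Conversion rate (%)")
    fig.tight_layout()
    fig.savefig(outdir / "cusum.png", dpi=120)
    plt.close(fig)
    names.append("cusum.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(dca.thresholds, dca.net_benefit_model, label="FIT model")
    ax.plot(dca.thresholds, dca.net_benefit_all, label="treat all", ls="--")
    ax.plot(dca.thresholds, dca.net_benefit_none, label="treat none", ls=":")
    ax.set_ylim(-0.05, dca.prevalence * 1.3)
    ax.set_xlabel("Threshold probability $p_t$")
    ax.set_ylabel("Net benefit (TP per patient)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "dca.png", dpi=120)
    plt.close(fig)
    names.append("dca.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(money.fit_grid, money.net_benefit_gbp)
    for t, d in steepest_declines(money, k=5):
        ax.axvline(t, color="red", ls="--", lw=0.6)
    ax.set_xscale("log")
    ax.set_xlabel("FIT threshold (µg/g)")
    ax.set_ylabel("Net benefit per patient (GBP units)")
    fig.tight_layout()
    fig.savefig(outdir / "monetary.png", dpi=120)
    plt.close(fig)
    names.append("monetary.png")
    return names
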