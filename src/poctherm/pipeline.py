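"""End-to-end analysis: from a site compilation to the temperature-effect test.

Stages, in order:

1. high-POC-deposition site filter (700 km / 1% seafloor POC / no
   Mediterranean sites);
2. age-depth models (chronologies with reversals rejected);
3. least-squares geotherms with quality control;
4. predicted labile-POC curves and temperature scores for QC-passing sites;
5. partition into low/middle/high temperature sets (lowest and highest 40%
   of scores by default);
6. annotation of POC points with ages and local sedimentation rates;
7. target lognormal for sedimentation rates (fit over *all* filtered sites
   with an age model, not just the scored ones) and distribution-matching
   weights per set;
8. equal-count-bin weighted POC-age curves with bootstrap bands, plus
   interval averages (1-2 Ma and 5-10 Ma by default);
9. Monte Carlo randomization test of the late-interval difference.

Each stage is exposed as a function so the command-line interface and the
analysis drivers can re-run stages from persisted intermediates;
:func:`run_full_analysis` composes them and is deterministic for a fixed
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import pocstats
from .agemodel import AgeModel, build_age_models
from .kinetics import ArrheniusParams, predicted_poc_curve
from .pocstats import TargetDistribution
from .sitedata import Dataset, filter_high_poc_sites
from .selection import SitePartition, partition_sites
from .significance import RandomizationResult, randomization_test
from .thermal import GeothermFit, fit_geotherm, qc_geotherm

__all__ = ["QCParams", "RunConfig", "AnalysisResult", "run_full_analysis",
           "fit_geotherms", "score_sites", "scored_points"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    min_points: int = 2
    min_r2: float = 0.95
    max_sft_offset: float = 2.0  # degC


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the full analysis (defaults are the study conditions)."""

    arrhenius: ArrheniusParams = field(default_factory=ArrheniusParams)
    qc: QCParams = field(default_factory=QCParams)
    max_distance_km: float = 700.0
    min_seafloor_poc: float = 1.0
    fraction: float = 0.40  # share of sites in each temperature set
    n_ages: int = 100
    n_steps: int = 200
    global_bin_target: int = 250  # points per bin, all-site curve
    set_bin_target: int = 70  # points per bin, per-set curves
    n_boot: int = 1000
    boot_level: float = 0.68
    n_rand_iter: int = 1000
    early_interval: tuple[float, float] = (1.0, 2.0)
    late_interval: tuple[float, float] = (5.0, 10.0)
    max_weight: float = 20.0

    def __post_init__(self):
        if not 0 < self.fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        for name in ("n_ages", "n_steps", "global_bin_target", "set_bin_target",
                     "n_boot", "n_rand_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnalysisResult:
    geotherms: pd.DataFrame
    scores: pd.DataFrame
    partition: SitePartition
    points: pd.DataFrame  # annotated POC points with set membership
    target: TargetDistribution
    global_series: pd.DataFrame
    low_series: pd.DataFrame
    high_series: pd.DataFrame
    interval_summary: pd.DataFrame
    randomization: RandomizationResult
    summary: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.geotherms.to_csv(outdir / "geotherms.csv", index=False)
        self.scores.to_csv(outdir / "scores.csv", index=False)
        membership = pd.DataFrame(
            {
                "site_id": list(self.partition.ranking),
                "set": [
                    "low" if s in self.partition.low_set
                    else "high" if s in self.partition.high_set else "mid"
                    for s in self.partition.ranking
                ],
            }
        )
        membership.to_csv(outdir / "partition.csv", index=False)
        self.points.to_csv(outdir / "points.csv", index=False)
        self.global_series.to_csv(outdir / "curve_global.csv", index=False)
        self.low_series.to_csv(outdir / "curve_low.csv", index=False)
        self.high_series.to_csv(outdir / "curve_high.csv", index=False)
        self.interval_summary.to_csv(outdir / "interval_averages.csv", index=False)
        pd.DataFrame({"null_diff_pct": self.randomization.null_diffs}).to_csv(
            outdir / "randomization_null.csv", index=False
        )
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=2) + "\n")


def fit_geotherms(
    dataset: Dataset, qc: QCParams = QCParams()
) -> tuple[pd.DataFrame, dict[str, GeothermFit]]:
    """Per-site geotherm fits with QC; returns the table and QC-passing fits."""
    rows = []
    passing: dict[str, GeothermFit] = {}
    bwt = dict(zip(dataset.sites["site_id"], dataset.sites["bwt_c"]))
    for site_id, grp in dataset.temps.groupby("site_id", sort=True):
        site_id = str(site_id)
        if len(grp) < 2 or grp["depth_mbsf"].nunique() < 2:
            rows.append({"site_id": site_id, "sft_c": np.nan, "gradient_c_per_m": np.nan,
                         "r2": np.nan, "n": len(grp), "qc_pass": False,
                         "qc_reasons": "too_few_points"})
            continue
        fit = fit_geotherm(site_id, grp["depth_mbsf"].to_numpy(), grp["temp_c"].to_numpy())
        qc_res = qc_geotherm(
            fit, float(bwt.get(site_id, np.nan)),
            min_points=qc.min_points, min_r2=qc.min_r2, max_sft_offset=qc.max_sft_offset,
        )
        if qc_res.passed:
            passing[site_id] = fit
        rows.append(
            {"site_id": site_id, "sft_c": fit.seafloor_temp,
             "gradient_c_per_m": fit.gradient, "r2": fit.r_squared, "n": fit.n_points,
             "qc_pass": qc_res.passed, "qc_reasons": ";".join(qc_res.reasons)}
        )
    return pd.DataFrame(rows), passing


def score_sites(
    age_models: Mapping[str, AgeModel],
    fits: Mapping[str, GeothermFit],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Temperature scores for sites that have both an age model and a QC-passing
    geotherm; one row per site with the score and modelled G at 10 Ma."""
    rows = []
    for site_id in sorted(set(age_models) & set(fits)):
        curve = predicted_poc_curve(
            age_models[site_id], fits[site_id], config.arrhenius,
            n_ages=config.n_ages, n_steps=config.n_steps,
        )
        rows.append({"site_id": site_id, "score": curve.score, "G_at_10Ma": float(curve.G[-1])})
    return pd.DataFrame(rows, columns=["site_id", "score", "G_at_10Ma"])


def scored_points(
    dataset: Dataset, config: RunConfig = RunConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, TargetDistribution, dict[str, AgeModel]]:
    """Filter, age models, geotherms, scores, annotated points and the target.

    Returns (scores, annotated points at scored sites, target lognormal fitted
    over all filtered sites with age models, age models).  This is the common
    prefix of the full analysis and of the randomization studies.
    """
    filtered = filter_high_poc_sites(dataset, config.max_distance_km, config.min_seafloor_poc)
    age_models, rejected = build_age_models(filtered.agenodes)
    if rejected:
        logger.info("rejected %d age model(s): %s", len(rejected), sorted(rejected))
    _, fits = fit_geotherms(filtered, config.qc)
    scores = score_sites(age_models, fits, config)
    all_points, _ = pocstats.annotate_points(filtered, age_models)
    target = pocstats.fit_target_lognormal(all_points["sed_rate_m_per_ma"])
    scored = all_points[all_points["site_id"].isin(set(scores["site_id"]))].reset_index(drop=True)
    return scores, scored, target, age_models


def _set_series(points, target, common_range, config, rng):
    tgt = TargetDistribution(target.log_mean, target.log_sd, common_range)
    weights = pocstats.compute_weights(
        points["sed_rate_m_per_ma"].to_numpy(), tgt, max_weight=config.max_weight
    )
    edges = pocstats.equal_count_bins(points["age_ma"], config.set_bin_target)
    series = pocstats.weighted_series(
        points, weights, edges, n_resamples=config.n_boot, level=config.boot_level, rng=rng
    )
    return weights, series


def run_full_analysis(
    dataset: Dataset,
    config: RunConfig = RunConfig(),
    seed: int = 0,
    outdir=None,
) -> AnalysisResult:
    """Run every stage on a dataset and bundle the tables and headline numbers."""
    rng = np.random.default_rng(seed)
    boot_seed, rand_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    filtered = filter_high_poc_sites(dataset, config.max_distance_km, config.min_seafloor_poc)
    age_models, _ = build_age_models(filtered.agenodes)
    geotherm_table, fits = fit_geotherms(filtered, config.qc)
    scores_df = score_sites(age_models, fits, config)
    if len(scores_df) < 2:
        raise RuntimeError("fewer than 2 scored sites; cannot partition")
    scores = dict(zip(scores_df["site_id"], scores_df["score"]))
    partition = partition_sites(scores, config.fraction)

    all_points, _ = pocstats.annotate_points(filtered, age_models)
    target = pocstats.fit_target_lognormal(all_points["sed_rate_m_per_ma"])

    points = all_points.copy()
    points["set"] = [
        "low" if s in partition.low_set
        else "high" if s in partition.high_set
        else "mid" if s in partition.middle_set else "unscored"
        for s in points["site_id"]
    ]
    low_pts = points[points["set"] == "low"].reset_index(drop=True)
    high_pts = points[points["set"] == "high"].reset_index(drop=True)
    if low_pts.empty or high_pts.empty:
        raise RuntimeError("a temperature set has no annotated POC points")

    boot_rng = np.random.default_rng(boot_seed)
    global_edges = pocstats.equal_count_bins(points["age_ma"], config.global_bin_target)
    global_series = pocstats.weighted_series(
        points, np.ones(len(points)), global_edges,
        n_resamples=config.n_boot, level=config.boot_level, rng=boot_rng,
    )
    common = pocstats.common_rate_range(
        low_pts["sed_rate_m_per_ma"], high_pts["sed_rate_m_per_ma"]
    )
    low_w, low_series = _set_series(low_pts, target, common, config, boot_rng)
    high_w, high_series = _set_series(high_pts, target, common, config, boot_rng)

    interval_rows = []
    for label, (lo, hi) in (("early", config.early_interval), ("late", config.late_interval)):
        for set_name, pts, w in (("low", low_pts, low_w), ("high", high_pts, high_w)):
            interval_rows.append(
                {"interval": label, "age_lo": lo, "age_hi": hi, "set": set_name,
                 "weighted_mean_poc_pct": pocstats.interval_average(pts, w, lo, hi),
                 "n_points": int(((pts["age_ma"] >= lo) & (pts["age_ma"] <= hi)).sum())}
            )
    interval_summary = pd.DataFrame(interval_rows)

    scored = points[points["site_id"].isin(set(scores))].reset_index(drop=True)
    randomization = randomization_test(
        scores, scored, target,
        fraction=config.fraction, n_iter=config.n_rand_iter, seed=rand_seed,
        age_interval=config.late_interval, max_weight=config.max_weight,
    )

    def _interval(label, set_name):
        row = interval_summary[
            (interval_summary["interval"] == label) & (interval_summary["set"] == set_name)
        ]
        return float(row["weighted_mean_poc_pct"].iloc[0])

    summary = {
        "n_sites_input": int(len(dataset.sites)),
        "n_sites_filtered": int(len(filtered.sites)),
        "n_sites_with_age_model": int(len(age_models)),
        "n_sites_scored": int(len(scores_df)),
        "n_low_sites": len(partition.low_set),
        "n_high_sites": len(partition.high_set),
        "low_poc_early_pct": _interval("early", "low"),
        "high_poc_early_pct": _interval("early", "high"),
        "low_poc_late_pct": _interval("late", "low"),
        "high_poc_late_pct": _interval("late", "high"),
        "observed_diff_pct": randomization.observed_diff,
        "p_value": randomization.p_value,
        "n_rand_iter": randomization.n_iter,
        "mean_log_sed_rate_low_m_per_ma": float(
            np.exp(np.mean(np.log(low_pts["sed_rate_m_per_ma"])))
        ),
        "mean_log_sed_rate_high_m_per_ma": float(
            np.exp(np.mean(np.log(high_pts["sed_rate_m_per_ma"])))
        ),
        "weight_retained_low_pct": float(100 * np.mean(low_w > 0)),
        "weight_retained_high_pct": float(100 * np.mean(high_w > 0)),
        "seed": int(seed),
        "config": {
            "fraction": config.fraction,
            "arrhenius_A_per_ma": config.arrhenius.A,
            "arrhenius_Ea_j_per_mol": config.arrhenius.Ea,
        },
    }

    result = AnalysisResult(
        geotherms=geotherm_table, scores=scores_df, partition=partition,
        points=points, target=target, global_series=global_series,
        low_series=low_series, high_series=high_series,
        interval_summary=interval_summary, randomization=randomization,
        summary=summary,
    )
    if outdir is not None:
        result.write(outdir)
    return result
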