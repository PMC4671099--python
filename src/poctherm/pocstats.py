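"""Weighted POC-versus-age statistics.

This module turns per-site POC measurements into comparable POC-age curves:

* **Annotation** — each measurement acquires a sediment age and a local
  sedimentation rate from its site's age-depth model.
* **Equal-count age bins** — age intervals are chosen so each holds the same
  number of data points, which keeps the binned averages from being dominated
  by densely sampled ages.
* **Distribution-matching weights** — sets of sites selected by temperature
  score end up with different sedimentation-rate distributions, and
  sedimentation rate itself affects POC deposition and preservation.  Each
  point therefore receives a weight equal to the ratio of a common *target*
  lognormal density to the set's own (kernel-smoothed) density at that
  point's log sedimentation rate, so weighted averages in every set behave
  as if rates followed the same target distribution.  Weights are zeroed
  outside the rate range spanned by both sets, so both sets are compared
  over the same rates.
* **Bootstrap bands** — uncertainty of each binned average is the central
  interval (default 68%, i.e. +-1 sigma for a normal) of weighted means over
  resamples of the points with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .agemodel import AgeModel
from .sitedata import Dataset

__all__ = [
    "TargetDistribution",
    "annotate_points",
    "equal_count_bins",
    "assign_bins",
    "fit_target_lognormal",
    "common_rate_range",
    "compute_weights",
    "weighted_binned_average",
    "interval_average",
    "bootstrap_band",
    "weighted_series",
]

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["site_id", "depth_mbsf", "poc_pct", "method", "age_ma", "sed_rate_m_per_ma"]


@dataclass(frozen=True)
class TargetDistribution:
    """Lognormal target for sedimentation rates (natural-log parameters)."""

    log_mean: float  # mean of ln(rate, m/Ma)
    log_sd: float
    common_range: tuple[float, float] | None = None  # (min, max) rate, m/Ma

    def log_density(self, log_rate):
        return stats.norm.pdf(log_rate, loc=self.log_mean, scale=self.log_sd)


def annotate_points(
    dataset: Dataset, age_models: Mapping[str, AgeModel]
) -> tuple[pd.DataFrame, int]:
    """Attach age (Ma) and local sedimentation rate (m/Ma) to every POC point.

    Points at sites without a valid age model are dropped; the second return
    value counts them.
    """
    frames = []
    n_dropped = 0
    for site_id, grp in dataset.poc.groupby("site_id", sort=True):
        model = age_models.get(str(site_id))
        if model is None:
            n_dropped += len(grp)
            continue
        depths = grp["depth_mbsf"].to_numpy(dtype=float)
        out = grp.copy()
        out["age_ma"] = model.age_at_depth(depths)
        out["sed_rate_m_per_ma"] = model.sedimentation_rate_at(depths)
        frames.append(out)
    if frames:
        points = pd.concat(frames, ignore_index=True)[POINT_COLUMNS]
    else:
        points = pd.DataFrame(columns=POINT_COLUMNS)
    if n_dropped:
        logger.info("annotate_points: dropped %d points at sites without age models", n_dropped)
    return points, n_dropped


def equal_count_bins(ages, target_per_bin: int) -> np.ndarray:
    """Age-bin edges such that each bin holds ``target_per_bin`` points.

    The points are sorted by age and cut into ``floor(n / target_per_bin)``
    contiguous rank blocks; interior edges sit midway between the ages that
    straddle each cut, so every bin holds exactly ``target_per_bin`` points
    (ties permitting) except the last, which absorbs the remainder.  With
    fewer points than ``target_per_bin`` a single bin is returned.
    """
    a = np.sort(np.asarray(ages, dtype=float))
    if a.size == 0:
        raise ValueError("no points to bin")
    if target_per_bin < 2:
        raise ValueError("target_per_bin must be >= 2")
    n_bins = a.size // target_per_bin
    if n_bins < 1:
        logger.warning(
            "equal_count_bins: only %d points for target %d; single bin", a.size, target_per_bin
        )
        n_bins = 1
    cuts = [(a[k * target_per_bin - 1] + a[k * target_per_bin]) / 2 for k in range(1, n_bins)]
    return np.array([a[0], *cuts, a[-1]])


def assign_bins(ages, edges: np.ndarray) -> np.ndarray:
    """Bin index (0-based) per age; both outer edges inclusive, -1 if outside."""
    a = np.asarray(ages, dtype=float)
    idx = np.searchsorted(edges, a, side="right") - 1
    idx[a == edges[-1]] = len(edges) - 2  # top edge belongs to last bin
    idx[(a < edges[0]) | (a > edges[-1])] = -1
    return idx


def fit_target_lognormal(sed_rates, min_points: int = 10) -> TargetDistribution:
    """Fit the target lognormal: mean/sd of ln(rate) over all supplied points."""
    r = np.asarray(sed_rates, dtype=float)
    r = r[np.isfinite(r) & (r > 0)]
    if r.size < min_points:
        raise ValueError(f"need >= {min_points} positive sedimentation rates")
    lr = np.log(r)
    sd = float(np.std(lr, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(lr)))):  # zero up to roundoff
        raise ValueError("degenerate sedimentation-rate sample (zero variance)")
    return TargetDistribution(log_mean=float(np.mean(lr)), log_sd=sd)


def common_rate_range(rates_a, rates_b) -> tuple[float, float]:
    """Rate interval spanned by *both* samples: (max of mins, min of maxes)."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if not lo < hi:
        raise ValueError("samples share no common sedimentation-rate range")
    return float(lo), float(hi)


def _gaussian_kde_at(sample: np.ndarray, x: np.ndarray, n_grid: int = 512) -> np.ndarray:
    """Gaussian kernel density (Silverman bandwidth) of ``sample`` at ``x``.

    Evaluated on a fine grid spanning the sample +-4 bandwidths and linearly
    interpolated; grid resolution is far below the bandwidth so the
    interpolation error is negligible.
    """
    n = sample.size
    h = np.std(sample, ddof=1) * (0.75 * n) ** (-0.2)  # Silverman, d = 1
    grid = np.linspace(sample.min() - 4 * h, sample.max() + 4 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - sample[None, :]) / h) ** 2).sum(axis=1)
    dens /= n * h * np.sqrt(2 * np.pi)
    return np.interp(x, grid, dens, left=0.0, right=0.0)


def compute_weights(
    sed_rates,
    target: TargetDistribution,
    max_weight: float = 20.0,
) -> np.ndarray:
    """Distribution-matching weights for one set of POC points.

    weight_i = target_density(ln r_i) / sample_density(ln r_i), where the
    sample density is a Gaussian kernel estimate on the natural-log scale
    with Silverman's bandwidth.  Weights are zero outside the target's
    ``common_range``, capped at ``max_weight`` against density-tail
    instability, and rescaled so nonzero weights average 1 (rescaling leaves
    every weighted mean unchanged).
    """
    r = np.asarray(sed_rates, dtype=float)
    if r.size == 0 or np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("sedimentation rates must be finite and positive")
    lr = np.log(r)
    if np.ptp(lr) == 0:
        raise ValueError("degenerate sample: all sedimentation rates equal")
    sample_density = _gaussian_kde_at(lr, lr)
    target_density = target.log_density(lr)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sample_density > 0, target_density / sample_density, np.inf)
    n_capped = int(np.sum(w > max_weight))
    if n_capped:
        logger.warning("compute_weights: capped %d weight(s) at %g", n_capped, max_weight)
        w = np.minimum(w, max_weight)
    if target.common_range is not None:
        lo, hi = target.common_range
        w[(r < lo) | (r > hi)] = 0.0
    nz = w > 0
    if nz.any():
        w[nz] /= w[nz].mean()
    return w


def weighted_binned_average(
    points: pd.DataFrame, weights, edges: np.ndarray
) -> pd.DataFrame:
    """Weighted mean POC per age bin.

    Returns one row per bin with columns age_lo, age_hi, mean_age (weighted),
    weighted_mean_poc, n_points (nonzero-weight points), band_lo/band_hi
    placeholders (NaN until :func:`bootstrap_band` fills them).  Bins whose
    total weight is zero report NaN means.
    """
    w = np.asarray(weights, dtype=float)
    ages = points["age_ma"].to_numpy(dtype=float)
    poc = points["poc_pct"].to_numpy(dtype=float)
    idx = assign_bins(ages, edges)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        wb, ab, pb = w[in_bin], ages[in_bin], poc[in_bin]
        total = wb.sum()
        if total > 0:
            mean_age = float(np.average(ab, weights=wb))
            mean_poc = float(np.average(pb, weights=wb))
        else:
            mean_age = float(np.mean(ab)) if ab.size else np.nan
            mean_poc = np.nan
        rows.append(
            {
                "age_lo": float(edges[b]),
                "age_hi": float(edges[b + 1]),
                "mean_age": mean_age,
                "weighted_mean_poc": mean_poc,
                "n_points": int(np.sum(in_bin & (w > 0))),
                "band_lo": np.nan,
                "band_hi": np.nan,
            }
        )
    return pd.DataFrame(rows)


def interval_average(points: pd.DataFrame, weights, age_lo: float, age_hi: float) -> float:
    """Weighted mean POC over points with age in [age_lo, age_hi]; NaN if empty."""
    w = np.asarray(weights, dtype=float)
    ages = points["age_ma"].to_numpy(dtype=float)
    in_interval = (ages >= age_lo) & (ages <= age_hi)
    total = w[in_interval].sum()
    if not in_interval.any() or total == 0:
        logger.warning("interval_average: no weighted points in [%g, %g] Ma", age_lo, age_hi)
        return float("nan")
    return float(np.average(points["poc_pct"].to_numpy(dtype=float)[in_interval],
                            weights=w[in_interval]))


def bootstrap_band(
    poc,
    weights,
    n_resamples: int = 1000,
    level: float = 0.68,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Central bootstrap interval of the weighted mean of one bin's points.

    Points are resampled with replacement (weights travel with their points)
    and the weighted mean recomputed per resample; the band is the central
    ``level`` interval of those means (16th/84th percentiles at 0.68).
    """
    p = np.asarray(poc, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.size < 2:
        raise ValueError("need >= 2 points to bootstrap")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, p.size, size=(n_resamples, p.size))
    wr = w[idx]
    totals = wr.sum(axis=1)
    means = np.full(n_resamples, np.nan)
    ok = totals > 0
    means[ok] = (wr[ok] * p[idx][ok]).sum(axis=1) / totals[ok]
    means = means[np.isfinite(means)]
    if means.size == 0:
        return float("nan"), float("nan")
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(means, [tail, 100 - tail])
    return float(lo), float(hi)


def weighted_series(
    points: pd.DataFrame,
    weights,
    edges: np.ndarray,
    n_resamples: int = 1000,
    level: float = 0.68,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binned weighted averages with bootstrap bands filled in."""
    series = weighted_binned_average(points, weights, edges)
    w = np.asarray(weights, dtype=float)
    ages = points["age_ma"].to_numpy(dtype=float)
    poc = points["poc_pct"].to_numpy(dtype=float)
    idx = assign_bins(ages, edges)
    rng = np.random.default_rng() if rng is None else rng
    for b in range(len(series)):
        in_bin = idx == b
        if np.sum(in_bin) >= 2 and w[in_bin].sum() > 0:
            lo, hi = bootstrap_band(poc[in_bin], w[in_bin], n_resamples, level, rng)
            series.loc[b, ["band_lo", "band_hi"]] = lo, hi
    return series
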