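"""Equal-count binning, distribution-matching weights, weighted averages,
and bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest

import poctherm as pt
from poctherm import pocstats
from poctherm.pocstats import TargetDistribution, assign_bins


def _points(ages, poc=None, rates=None):
    n = len(ages)
    return pd.DataFrame(
        {
            "site_id": ["S"] * n,
            "depth_mbsf": np.arange(n, dtype=float),
            "poc_pct": poc if poc is not None else np.ones(n),
            "method": ["difference"] * n,
            "age_ma": ages,
            "sed_rate_m_per_ma": rates if rates is not None else np.full(n, 100.0),
        }
    )


class TestAnnotatePoints:
    def test_age_and_rate_from_model(self, simple_model):
        ds = pt.Dataset(
            sites=pd.DataFrame([{"site_id": "SIMPLE", "lat": 0, "lon": 0, "water_depth_m": 1000,
                                 "dist_land_km": 10, "seafloor_poc_pct": 1, "bwt_c": 2,
                                 "mediterranean": False}]),
            poc=pd.DataFrame([{"site_id": "SIMPLE", "depth_mbsf": 50.0, "poc_pct": 0.7,
                               "method": "difference"}]),
            temps=pd.DataFrame([], columns=["site_id", "depth_mbsf", "temp_c"]),
            agenodes=pd.DataFrame([], columns=["site_id", "depth_mbsf", "age_ma"]),
        )
        points, dropped = pt.annotate_points(ds, {"SIMPLE": simple_model})
        assert dropped == 0
        assert points.loc[0, "age_ma"] == pytest.approx(0.5)
        assert points.loc[0, "sed_rate_m_per_ma"] == pytest.approx(100.0)

    def test_sites_without_models_dropped_and_conserved(self, small_ensemble):
        from poctherm.agemodel import build_age_models

        models, _ = build_age_models(small_ensemble.dataset.agenodes)
        half = {k: models[k] for k in sorted(models)[: len(models) // 2]}
        points, dropped = pt.annotate_points(small_ensemble.dataset, half)
        assert len(points) + dropped == len(small_ensemble.dataset.poc)
        assert dropped > 0


class TestEqualCountBins:
    def test_exact_division(self, rng):
        ages = rng.uniform(0, 10, 500)
        edges = pt.equal_count_bins(ages, 250)
        counts = np.bincount(assign_bins(ages, edges), minlength=len(edges) - 1)
        assert counts.tolist() == [250, 250]

    def test_remainder_folds_into_last_bin(self, rng):
        ages = rng.uniform(0, 10, 510)
        edges = pt.equal_count_bins(ages, 250)
        counts = np.bincount(assign_bins(ages, edges), minlength=len(edges) - 1)
        assert counts.tolist() == [250, 260]

    def test_counts_always_sum_to_n(self, rng):
        for n in (37, 100, 1001):
            ages = rng.uniform(0, 10, n)
            edges = pt.equal_count_bins(ages, 70)
            assert np.bincount(assign_bins(ages, edges)).sum() == n

    def test_fewer_points_than_target_gives_single_bin(self, rng):
        edges = pt.equal_count_bins(rng.uniform(0, 10, 5), 250)
        assert len(edges) == 2


class TestTargetLognormal:
    def test_recovers_parameters(self, rng):
        mu, sd = np.log(100.0), 0.8
        rates = rng.lognormal(mu, sd, 5000)
        target = pt.fit_target_lognormal(rates)
        se_mu, se_sd = sd / np.sqrt(5000), sd / np.sqrt(2 * 5000)
        assert abs(target.log_mean - mu) < 3 * se_mu
        assert abs(target.log_sd - sd) < 3 * se_sd

    def test_order_invariant(self, rng):
        rates = rng.lognormal(4.0, 0.5, 200)
        t1 = pt.fit_target_lognormal(rates)
        t2 = pt.fit_target_lognormal(rates[::-1])
        assert t1.log_mean == t2.log_mean and t1.log_sd == t2.log_sd

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            pt.fit_target_lognormal(np.full(50, 100.0))


class TestComputeWeights:
    def test_matched_sample_weights_near_one(self, rng):
        target = TargetDistribution(np.log(100.0), 0.8, common_range=(1.0, 1e5))
        rates = rng.lognormal(target.log_mean, target.log_sd, 4000)
        w = pt.compute_weights(rates, target)
        assert w.mean() == pytest.approx(1.0)
        assert np.quantile(np.abs(w - 1), 0.9) < 0.35  # within kernel error

    def test_zero_outside_common_range(self, rng):
        target = TargetDistribution(np.log(100.0), 0.8, common_range=(50.0, 500.0))
        rates = np.array([10.0, 100.0, 1000.0, 120.0, 80.0])
        w = pt.compute_weights(rates, target)
        assert w[0] == 0.0 and w[2] == 0.0
        assert np.all(w[[1, 3, 4]] > 0)
        assert w[w > 0].mean() == pytest.approx(1.0)

    def test_importance_weighting_recovers_target_mean(self, rng):
        """Weighted mean of ln(rate) of a biased sample matches the target."""
        target = TargetDistribution(np.log(100.0), 0.8, common_range=(0.1, 1e6))
        biased = rng.lognormal(np.log(100.0) + 0.5, 0.8, 5000)  # oversampled fast sites
        w = pt.compute_weights(biased, target)
        x = np.log(biased)
        xbar = np.average(x, weights=w)
        se = np.sqrt(np.sum((w * (x - xbar)) ** 2)) / w.sum()
        assert abs(xbar - target.log_mean) < 3 * max(se, 0.01)

    def test_degenerate_rates_rejected(self):
        target = TargetDistribution(np.log(100.0), 0.8)
        with pytest.raises(ValueError):
            pt.compute_weights(np.full(10, 100.0), target)


class TestWeightedAverages:
    def test_unit_weights_reduce_to_plain_bin_means(self, rng):
        ages = rng.uniform(0, 10, 200)
        poc = rng.uniform(0.2, 1.5, 200)
        pts = _points(ages, poc)
        edges = pt.equal_count_bins(ages, 100)
        series = pt.weighted_binned_average(pts, np.ones(200), edges)
        idx = assign_bins(ages, edges)
        for b in range(2):
            assert series.loc[b, "weighted_mean_poc"] == pytest.approx(poc[idx == b].mean())

    @pytest.mark.parametrize("weights, expected", [([1.0, 1.0], 0.6), ([3.0, 1.0], 0.5)])
    def test_hand_weighted_means(self, weights, expected):
        pts = _points([1.0, 2.0], poc=[0.4, 0.8])
        series = pt.weighted_binned_average(pts, np.array(weights), np.array([0.0, 3.0]))
        assert series.loc[0, "weighted_mean_poc"] == pytest.approx(expected)

    def test_interval_average_plain_mean_and_empty(self):
        pts = _points([1.0, 1.5, 2.0], poc=[0.3, 0.6, 0.9])
        assert pt.interval_average(pts, np.ones(3), 0.0, 3.0) == pytest.approx(0.6)
        assert np.isnan(pt.interval_average(pts, np.ones(3), 5.0, 10.0))

    def test_interval_agrees_with_single_spanning_bin(self, rng):
        ages = rng.uniform(2.0, 4.0, 150)
        poc = rng.uniform(0.1, 1.0, 150)
        w = rng.uniform(0.5, 2.0, 150)
        pts = _points(ages, poc)
        series = pt.weighted_binned_average(pts, w, np.array([2.0, 4.0]))
        assert series.loc[0, "weighted_mean_poc"] == pytest.approx(
            pt.interval_average(pts, w, 2.0, 4.0)
        )

    def test_zero_weight_bin_reported_missing(self):
        pts = _points([1.0, 2.0], poc=[0.4, 0.8])
        series = pt.weighted_binned_average(pts, np.zeros(2), np.array([0.0, 3.0]))
        assert np.isnan(series.loc[0, "weighted_mean_poc"])


class TestBootstrapBand:
    def test_identical_points_zero_width(self, rng):
        lo, hi = pt.bootstrap_band(np.full(20, 0.7), np.ones(20), rng=rng)
        assert lo == hi == pytest.approx(0.7)

    def test_fixed_seed_reproducible(self):
        poc = np.random.default_rng(5).uniform(0, 1, 30)
        b1 = pt.bootstrap_band(poc, np.ones(30), rng=np.random.default_rng(99))
        b2 = pt.bootstrap_band(poc, np.ones(30), rng=np.random.default_rng(99))
        assert b1 == b2

    def test_width_scales_inverse_sqrt_n(self, rng):
        """Quadrupling n roughly halves the central-interval width."""
        n = 400
        x_small = rng.normal(0.8, 0.2, n)
        x_big = rng.normal(0.8, 0.2, 4 * n)
        lo1, hi1 = pt.bootstrap_band(x_small, np.ones(n), n_resamples=1000, rng=rng)
        lo2, hi2 = pt.bootstrap_band(x_big, np.ones(4 * n), n_resamples=1000, rng=rng)
        ratio = (hi1 - lo1) / (hi2 - lo2)
        assert 1.6 < ratio < 2.4

    def test_band_in_series(self, rng):
        ages = rng.uniform(0, 10, 300)
        poc = rng.uniform(0.2, 1.2, 300)
        pts = _points(ages, poc)
        edges = pt.equal_count_bins(ages, 100)
        series = pt.weighted_series(pts, np.ones(300), edges, n_resamples=200, rng=rng)
        assert (series["band_lo"] <= series["weighted_mean_poc"]).all()
        assert (series["band_hi"] >= series["weighted_mean_poc"]).all()
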