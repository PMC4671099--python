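"""Synthetic drill-site ensembles with the statistical structure of the
global ocean-drilling POC compilation.

Each generated site draws a sedimentation rate from a lognormal (median
~100 m/Ma, spanning roughly 8-2000 m/Ma), a seafloor temperature centred on
2.67 degC, and a linear geothermal gradient from a lognormal with median
0.053 degC/m.  POC deposited at the seafloor follows a time-varying history
(~1% today rising to a ~1.3% plateau by 1 Ma); a configurable labile share
of it then decays along the site's burial temperature history with *true*
Arrhenius parameters, and measurement noise is added with the
method-dependent standard deviation (+-0.1% acidified, +-0.25% by
difference).  In-situ temperature "measurements" are placed on the true
geotherm with small noise.  Hole depths are lognormal, so rapidly
accumulating sites rarely sample sediment older than ~4.5 Ma — the same
age-coverage asymmetry the real compilation shows.

Setting the true activation energy to zero makes the decay rate
temperature-independent (k = A at every site); the packaged
:meth:`SynthConfig.null` preset additionally sets A = 0, i.e. no
degradation at all, so expected POC at a fixed age is identical across cold
and warm sites — the null ensemble for calibration studies.

The per-point true labile fractions recorded in the truth table are
computed with a local fine-grid Simpson integrator that shares no code with
:func:`poctherm.kinetics.integrate_G`, so the truth table can serve as an
independent oracle for the pipeline's forward model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import simpson

from .sitedata import Dataset, ValidationReport, write_dataset

__all__ = ["SynthConfig", "SyntheticEnsemble", "deposition_history", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the study conditions.

    Scale parameters are strictly positive; ``true_Ea = 0`` disables the
    temperature dependence of degradation (``true_A = 0`` then disables
    degradation entirely).
    """

    n_sites: int = 100
    seed: int = 0

    # site-level draws
    log_sed_rate_mean: float = float(np.log(100.0))  # ln(m/Ma); median 100 m/Ma
    log_sed_rate_sd: float = 1.0  # spans ~8-2000 m/Ma over +-2.5 sd
    # within-site ln-rate variability between age-model segments; real
    # age models show order-of-magnitude rate changes down-hole, which is
    # why the observed low/high sets both span nearly the full rate range
    segment_rate_jitter_sd: float = 0.6
    age_model_node_ages: tuple[float, ...] = (0.0, 1.0, 2.0, 3.5, 5.0, 7.5, 10.0)  # Ma
    seafloor_temp_median: float = 2.67  # degC
    seafloor_temp_sd: float = 0.8
    seafloor_temp_min: float = -1.5  # freezing-point floor for bottom water
    log_gradient_median: float = float(np.log(0.053))  # ln(degC/m)
    log_gradient_sd: float = 0.8  # gradients span ~0.01 to >0.3 degC/m
    log_hole_depth_mean: float = float(np.log(300.0))  # ln(m)
    log_hole_depth_sd: float = 0.6
    hole_depth_range: tuple[float, float] = (60.0, 1200.0)

    # POC deposition history and partitioning of deposited carbon
    baseline_poc: float = 1.0  # % dry weight deposited today
    plateau_poc: float = 1.3  # % reached across the peak interval
    peak_interval: tuple[float, float] = (1.0, 2.0)  # Ma
    labile_fraction: float = 0.7  # share of deposited POC that can degrade
    # per-site lognormal factor on the deposition history (regional
    # productivity differences); real POC scatter at any age far exceeds
    # measurement noise, and this is its dominant source
    site_poc_log_sd: float = 0.4

    # true degradation kinetics
    true_A: float = 3e18  # 1/Ma
    true_Ea: float = 110_000.0  # J/mol; 0 => temperature-independent
    gas_constant: float = 8.314

    # sampling and noise
    sample_interval_m: float = 10.0
    max_sampled_age: float = 10.0  # Ma
    n_samples_per_site: int | None = None  # exchangeable-coverage variant (see below)
    p_difference_method: float = 0.5  # share of sites measured by TC - IC
    noise_sd_acidified: float = 0.1  # % POC
    noise_sd_difference: float = 0.25
    n_temp_measurements: tuple[int, int] = (3, 5)
    temp_noise_sd: float = 0.1  # degC
    bwt_noise_sd: float = 0.2  # degC offset of bottom-water temp from true sft

    # site metadata
    dist_land_range: tuple[float, float] = (10.0, 900.0)
    seafloor_poc_noise_sd: float = 0.1
    mediterranean_fraction: float = 0.0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        for name in (
            "log_sed_rate_sd", "seafloor_temp_sd", "log_gradient_sd",
            "log_hole_depth_sd", "baseline_poc", "plateau_poc",
            "sample_interval_m", "max_sampled_age",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.labile_fraction <= 1:
            raise ValueError("labile_fraction must be in (0, 1]")
        if self.true_A < 0 or self.true_Ea < 0:
            raise ValueError("true_A and true_Ea must be non-negative")
        # YAML round-trips tuples as lists; normalise
        for name in ("hole_depth_range", "peak_interval", "n_temp_measurements",
                     "dist_land_range", "age_model_node_ages"):
            v = getattr(self, name)
            if isinstance(v, list):
                object.__setattr__(self, name, tuple(v))
        nodes = np.asarray(self.age_model_node_ages, dtype=float)
        if nodes[0] != 0 or np.any(np.diff(nodes) <= 0) or nodes[-1] < self.max_sampled_age:
            raise ValueError(
                "age_model_node_ages must start at 0, increase strictly and "
                "reach max_sampled_age"
            )

    @classmethod
    def null(cls, **overrides) -> "SynthConfig":
        """Null ensemble: no degradation, hence no temperature effect on POC."""
        overrides.setdefault("true_A", 0.0)
        overrides.setdefault("true_Ea", 0.0)
        return cls(**overrides)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def deposition_history(age, config: SynthConfig):
    """Deposited POC (% dry weight) of sediment now ``age`` Ma old.

    Smoothly rises from ``baseline_poc`` at age 0 to ``plateau_poc`` at the
    start of the peak interval and stays there: any *decline* of synthetic
    POC at old ages is then attributable to degradation alone.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    x = np.clip(a / config.peak_interval[0], 0.0, 1.0)
    s = x * x * (3.0 - 2.0 * x)  # smoothstep
    dep = config.baseline_poc + (config.plateau_poc - config.baseline_poc) * s
    return float(dep) if np.ndim(age) == 0 else dep


def _true_labile_fraction(
    sample_ages: np.ndarray,
    node_depths: np.ndarray,
    node_ages: np.ndarray,
    seafloor_temp: float,
    gradient: float,
    config: SynthConfig,
    n_fine: int = 800,
) -> np.ndarray:
    """Independent fine-grid evaluation of G = exp(-int k dt) per sample age.

    Uses plain np.interp on the node arrays and Simpson integration on an
    ``n_fine + 1`` point grid; deliberately shares no code path with the
    pipeline's trapezoidal integrator.
    """
    a = np.asarray(sample_ages, dtype=float)
    if config.true_Ea == 0.0:
        return np.exp(-config.true_A * a)
    s = np.linspace(0.0, 1.0, n_fine + 1)[None, :]
    t = a[:, None] * s
    depth_now = np.interp(a, node_ages, node_depths)[:, None]
    depth = depth_now - np.interp(a[:, None] - t, node_ages, node_depths)
    temperature_k = seafloor_temp + gradient * np.maximum(depth, 0.0) + 273.15
    k = config.true_A * np.exp(-config.true_Ea / (config.gas_constant * temperature_k))
    integral = simpson(k, x=t, axis=1)
    return np.exp(-integral)


@dataclass
class SyntheticEnsemble:
    dataset: Dataset
    site_truth: pd.DataFrame  # site_id, sed_rate, seafloor_temp, gradient, hole_depth, method
    point_truth: pd.DataFrame  # site_id, depth_mbsf, age_ma, G_true, poc_true_pct
    config: SynthConfig

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_dataset(self.dataset, directory)
        self.site_truth.to_csv(directory / "site_truth.csv", index=False)
        self.point_truth.to_csv(directory / "point_truth.csv", index=False)
        self.config.to_yaml(directory / "config.yaml")


def generate_dataset(config: SynthConfig) -> SyntheticEnsemble:
    """Generate a seeded synthetic ensemble (bit-identical for a fixed seed)."""
    rng = np.random.default_rng(config.seed)
    site_rows, poc_rows, temp_rows, age_rows = [], [], [], []
    site_truth_rows, point_truth_rows = [], []

    for i in range(config.n_sites):
        site_id = f"S{i + 1:04d}"
        rate = float(rng.lognormal(config.log_sed_rate_mean, config.log_sed_rate_sd))
        sft = float(
            max(rng.normal(config.seafloor_temp_median, config.seafloor_temp_sd),
                config.seafloor_temp_min)
        )
        gradient = float(rng.lognormal(config.log_gradient_median, config.log_gradient_sd))
        hole = float(
            np.clip(rng.lognormal(config.log_hole_depth_mean, config.log_hole_depth_sd),
                    *config.hole_depth_range)
        )
        site_factor = float(rng.lognormal(0.0, config.site_poc_log_sd))
        method = (
            "difference" if rng.random() < config.p_difference_method else "acidified-direct"
        )
        noise_sd = (
            config.noise_sd_difference if method == "difference" else config.noise_sd_acidified
        )

        # piecewise-linear age model down to the maximum modelled age; each
        # age segment's rate jitters around the site rate (median preserved),
        # as depth-varying accumulation does in real age models
        node_ages = np.asarray(config.age_model_node_ages, dtype=float)
        seg_rates = rate * np.exp(
            rng.normal(0.0, config.segment_rate_jitter_sd, node_ages.size - 1)
        )
        node_depths = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(node_ages))])
        for z, a in zip(node_depths, node_ages):
            age_rows.append({"site_id": site_id, "depth_mbsf": z, "age_ma": a})

        # POC samples: by default every sample_interval_m down the hole (so
        # rapidly accumulating sites rarely reach old ages, as in the real
        # compilation); with n_samples_per_site set, a fixed number of samples
        # evenly spaced in age over the whole 0-10 Ma record instead, giving
        # every site identical age coverage (site-exchangeable ensembles for
        # calibration studies)
        if config.n_samples_per_site is not None:
            n_s = int(config.n_samples_per_site)
            ages = (np.arange(n_s) + 0.5) * config.max_sampled_age / n_s
            depths = np.interp(ages, node_ages, node_depths)
        else:
            max_depth = min(hole, node_depths[-1])
            depths = np.arange(config.sample_interval_m, max_depth, config.sample_interval_m)
            ages = np.interp(depths, node_depths, node_ages)
        if depths.size:
            G = _true_labile_fraction(
                ages, node_depths, node_ages, sft, gradient, config
            )
            dep = site_factor * deposition_history(ages, config)
            poc_true = (1.0 - config.labile_fraction) * dep + config.labile_fraction * dep * G
            measured = np.maximum(poc_true + rng.normal(0.0, noise_sd, depths.size), 0.0)
            for z, a, g, pt, pm in zip(depths, ages, G, poc_true, measured):
                poc_rows.append(
                    {"site_id": site_id, "depth_mbsf": float(z), "poc_pct": float(pm),
                     "method": method}
                )
                point_truth_rows.append(
                    {"site_id": site_id, "depth_mbsf": float(z), "age_ma": float(a),
                     "G_true": float(g), "poc_true_pct": float(pt)}
                )

        # in-situ temperatures on the true geotherm
        n_t = int(rng.integers(config.n_temp_measurements[0], config.n_temp_measurements[1] + 1))
        t_depths = np.linspace(0.15, 0.85, n_t) * hole
        t_meas = sft + gradient * t_depths + rng.normal(0.0, config.temp_noise_sd, n_t)
        for z, T in zip(t_depths, t_meas):
            temp_rows.append({"site_id": site_id, "depth_mbsf": float(z), "temp_c": float(T)})

        site_rows.append(
            {
                "site_id": site_id,
                "lat": float(rng.uniform(-70, 70)),
                "lon": float(rng.uniform(-180, 180)),
                "water_depth_m": float(rng.uniform(200, 5500)),
                "dist_land_km": float(rng.uniform(*config.dist_land_range)),
                "seafloor_poc_pct": float(
                    max(site_factor * config.baseline_poc
                        + rng.normal(0.0, config.seafloor_poc_noise_sd), 0.0)
                ),
                "bwt_c": float(sft + rng.normal(0.0, config.bwt_noise_sd)),
                "mediterranean": bool(rng.random() < config.mediterranean_fraction),
            }
        )
        site_truth_rows.append(
            {"site_id": site_id, "sed_rate_m_per_ma": rate, "seafloor_temp_c": sft,
             "gradient_c_per_m": gradient, "hole_depth_m": hole, "method": method,
             "site_poc_factor": site_factor}
        )

    dataset = Dataset(
        sites=pd.DataFrame(site_rows),
        poc=pd.DataFrame(poc_rows, columns=["site_id", "depth_mbsf", "poc_pct", "method"]),
        temps=pd.DataFrame(temp_rows, columns=["site_id", "depth_mbsf", "temp_c"]),
        agenodes=pd.DataFrame(age_rows, columns=["site_id", "depth_mbsf", "age_ma"]),
        validation=ValidationReport(),
    )
    site_truth = pd.DataFrame(site_truth_rows)
    point_truth = pd.DataFrame(
        point_truth_rows,
        columns=["site_id", "depth_mbsf", "age_ma", "G_true", "poc_true_pct"],
    )
    return SyntheticEnsemble(
        dataset=dataset, site_truth=site_truth, point_truth=point_truth, config=config
    )
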