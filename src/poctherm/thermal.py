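"""Linear geotherms and burial temperature histories.

In-situ sediment temperatures in scientific drill holes generally align on a
linear geotherm because the thermal conductivity of sediments varies little
with depth.  Each site's geotherm is estimated by ordinary least squares of
temperature on depth; the intercept is the seafloor temperature and the slope
the geothermal gradient (degC/m).  A quality-control step keeps only sites
with a well-defined, physically plausible gradient whose seafloor temperature
agrees with near-bottom water temperature.

The temperature history of a sediment parcel now found at the depth where
its age equals ``parcel_age`` is reconstructed by assuming (i) the present
gradient held throughout burial and (ii) the age model describes a steady
depth-age relation, so the parcel's depth at elapsed time t after deposition
is depth(parcel_age) - depth(parcel_age - t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .agemodel import AgeModel

__all__ = [
    "GeothermFit",
    "BurialHistory",
    "QCResult",
    "fit_geotherm",
    "qc_geotherm",
    "burial_temperature_history",
]


class GeothermError(ValueError):
    """Raised when a geotherm cannot be estimated."""


@dataclass(frozen=True)
class GeothermFit:
    """Least-squares linear geotherm: T(z) = seafloor_temp + gradient * z."""

    site_id: str
    seafloor_temp: float  # degC, intercept at 0 mbsf
    gradient: float  # degC per meter
    r_squared: float
    n_points: int

    def temperature_at(self, depth):
        return self.seafloor_temp + self.gradient * np.asarray(depth, dtype=float)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class BurialHistory:
    """Temperature experienced by one parcel from deposition (t=0) to present."""

    parcel_age: float  # Ma
    t: np.ndarray = field(repr=False)  # elapsed time since deposition, Ma
    depth: np.ndarray = field(repr=False)  # mbsf at each t
    temperature: np.ndarray = field(repr=False)  # degC at each t


def fit_geotherm(site_id: str, depths, temperatures) -> GeothermFit:
    """Ordinary least squares of temperature on depth.

    r_squared is defined as 1.0 for two-point fits (a line through two
    distinct depths is exact).  Requires at least two distinct depths.
    """
    z = np.asarray(depths, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if z.size != T.size or z.size < 2:
        raise GeothermError(f"{site_id}: need >= 2 temperature measurements")
    if np.ptp(z) == 0:
        raise GeothermError(f"{site_id}: zero depth variance")
    res = stats.linregress(z, T)
    r2 = 1.0 if z.size == 2 else float(res.rvalue) ** 2
    if not np.isfinite(r2):  # zero temperature variance: perfectly flat line
        r2 = 1.0
    return GeothermFit(
        site_id=site_id,
        seafloor_temp=float(res.intercept),
        gradient=float(res.slope),
        r_squared=r2,
        n_points=int(z.size),
    )


def qc_geotherm(
    fit: GeothermFit,
    bottom_water_temp: float,
    min_points: int = 2,
    min_r2: float = 0.95,
    max_sft_offset: float = 2.0,
) -> QCResult:
    """Quality control of a geotherm fit.

    Fails when the fit has too few points, is visibly nonlinear (r^2 below
    ``min_r2``, checked only when 3+ points make r^2 informative), has a
    non-positive gradient, or implies a seafloor temperature inconsistent
    with the near-bottom water temperature.
    """
    reasons: list[str] = []
    if fit.n_points < min_points:
        reasons.append("too_few_points")
    if fit.n_points >= 3 and fit.r_squared < min_r2:
        reasons.append("nonlinear")
    if fit.gradient <= 0:
        reasons.append("nonpositive_gradient")
    if np.isfinite(bottom_water_temp):
        if abs(fit.seafloor_temp - bottom_water_temp) > max_sft_offset:
            reasons.append("seafloor_temp_inconsistent")
    else:
        reasons.append("missing_bottom_water_temp")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def burial_temperature_history(
    age_model: AgeModel,
    fit: GeothermFit,
    parcel_age: float,
    n_steps: int = 200,
) -> BurialHistory:
    """Temperature history of the parcel whose present age is ``parcel_age``.

    Sampled on an evenly spaced grid of ``n_steps + 1`` elapsed times on
    [0, parcel_age].  A parcel_age of 0 yields a single seafloor sample.
    """
    if parcel_age < 0:
        raise ValueError("parcel_age must be >= 0")
    if parcel_age == 0:
        t = np.zeros(1)
    else:
        t = np.linspace(0.0, parcel_age, n_steps + 1)
    depth_now = age_model.depth_at_age(parcel_age)
    depth = depth_now - age_model.depth_at_age(parcel_age - t)
    depth = np.maximum(np.atleast_1d(depth), 0.0)
    temperature = fit.seafloor_temp + fit.gradient * depth
    return BurialHistory(parcel_age=float(parcel_age), t=t, depth=depth, temperature=temperature)
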