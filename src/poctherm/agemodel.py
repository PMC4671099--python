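"""Piecewise-linear age-depth models.

An age model maps burial depth (mbsf) to sediment age (Ma) by linear
interpolation between dated horizons ("nodes"), e.g. biostratigraphic or
magnetostratigraphic datums.  The model also provides the inverse mapping
(depth at a given age) and the local sedimentation rate, which is the slope
dz/da of the segment containing a depth.

Conventions
-----------
* A virtual surface node (0 mbsf, 0 Ma) is prepended when the shallowest
  node lies below the seafloor: freshly deposited sediment has zero age.
* Above the shallowest node the model interpolates from that surface node;
  below the deepest node it extrapolates with the last segment's slope,
  so any age is reachable at finite depth.
* Depths and ages must both be strictly increasing.  Age reversals mark an
  unreliable chronology and cause rejection rather than repair.
* A query exactly on a node belongs to the *deeper* adjacent segment for
  the purpose of the sedimentation rate (documented tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgeModel", "AgeModelError", "build_age_models"]


class AgeModelError(ValueError):
    """Raised for structurally invalid age models (too few nodes, reversals)."""


def _as_query(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


@dataclass(frozen=True)
class AgeModel:
    """Monotone piecewise-linear depth (mbsf) <-> age (Ma) mapping."""

    site_id: str
    depths: np.ndarray = field(repr=False)
    ages: np.ndarray = field(repr=False)

    @classmethod
    def from_nodes(cls, site_id: str, depths, ages) -> "AgeModel":
        """Validate nodes and build a model; reject non-monotone chronologies."""
        z = np.asarray(depths, dtype=float)
        a = np.asarray(ages, dtype=float)
        if z.shape != a.shape or z.ndim != 1:
            raise AgeModelError(f"{site_id}: depths and ages must be 1-D and aligned")
        order = np.argsort(z, kind="stable")
        z, a = z[order], a[order]
        if z.size and z[0] > 0:
            if a[0] <= 0:
                raise AgeModelError(f"{site_id}: first node below seafloor has non-positive age")
            z = np.concatenate([[0.0], z])
            a = np.concatenate([[0.0], a])
        if z.size < 2:
            raise AgeModelError(f"{site_id}: need at least 2 nodes")
        if np.any(np.diff(z) <= 0):
            raise AgeModelError(f"{site_id}: node depths must be strictly increasing")
        if np.any(np.diff(a) <= 0):
            raise AgeModelError(f"{site_id}: age reversal or stagnation in nodes")
        if np.any(z < 0) or np.any(a < 0):
            raise AgeModelError(f"{site_id}: negative node depth or age")
        z.setflags(write=False)
        a.setflags(write=False)
        return cls(site_id=site_id, depths=z, ages=a)

    # -- forward / inverse interpolation -------------------------------------

    def age_at_depth(self, depth):
        """Sediment age (Ma) at a depth (mbsf); scalar or array."""
        z = _as_query(depth, "depth")
        a = np.interp(z, self.depths, self.ages)
        beyond = z > self.depths[-1]
        if np.any(beyond):
            slope = (self.ages[-1] - self.ages[-2]) / (self.depths[-1] - self.depths[-2])
            a = np.where(beyond, self.ages[-1] + (z - self.depths[-1]) * slope, a)
        return float(a) if np.isscalar(depth) or np.ndim(depth) == 0 else a

    def depth_at_age(self, age):
        """Depth (mbsf) at which sediment has a given age (Ma); exact inverse."""
        a = _as_query(age, "age")
        z = np.interp(a, self.ages, self.depths)
        beyond = a > self.ages[-1]
        if np.any(beyond):
            slope = (self.depths[-1] - self.depths[-2]) / (self.ages[-1] - self.ages[-2])
            z = np.where(beyond, self.depths[-1] + (a - self.ages[-1]) * slope, z)
        return float(z) if np.isscalar(age) or np.ndim(age) == 0 else z

    def sedimentation_rate_at(self, depth):
        """Local sedimentation rate (m/Ma): slope of the segment holding `depth`.

        A query exactly at an interior node returns the deeper segment's rate;
        queries beyond the deepest node use the last segment.
        """
        z = _as_query(depth, "depth")
        idx = np.searchsorted(self.depths, z, side="right")
        idx = np.clip(idx, 1, self.depths.size - 1)
        rate = (self.depths[idx] - self.depths[idx - 1]) / (self.ages[idx] - self.ages[idx - 1])
        return float(rate) if np.isscalar(depth) or np.ndim(depth) == 0 else rate


def build_age_models(agenodes: pd.DataFrame) -> tuple[dict[str, AgeModel], dict[str, str]]:
    """Build per-site age models from an age-node table.

    Parameters
    ----------
    agenodes : DataFrame with columns site_id, depth_mbsf, age_ma.

    Returns
    -------
    (models, rejected) : dict site_id -> AgeModel for valid chronologies, and
        dict site_id -> reason for sites whose node sets were rejected.
    """
    models: dict[str, AgeModel] = {}
    rejected: dict[str, str] = {}
    for site_id, grp in agenodes.groupby("site_id", sort=True):
        try:
            models[str(site_id)] = AgeModel.from_nodes(
                str(site_id), grp["depth_mbsf"].to_numpy(), grp["age_ma"].to_numpy()
            )
        except AgeModelError as exc:
            rejected[str(site_id)] = str(exc)
    return models, rejected
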