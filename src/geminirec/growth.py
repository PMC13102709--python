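"""Cube-root growth law for granular protein-assembly recorders.

A recorder particle grows by constant-rate addition of subunits onto its
facets, so its volume increases linearly in time and its radius follows

    r(t) = (K t + A)^(1/3)

where ``K`` is the volumetric growth-rate constant (radius-units^3 per
hour) and ``A`` is the cubed radius at ``t = 0``.  Because the map between
layer radius and deposition time is monotone, any radial position inside a
particle can be converted to the absolute time at which that layer was
laid down — the basis of temporal decoding.

Projected particle area ``A_px`` (pixels^2) is summarised by the *volume
index* ``A_px^(3/2)``, which is proportional to particle volume under
shape-preserving growth and therefore linear in time.  All fitting is done
on this linearized scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModel",
    "GrowthTrajectory",
    "GrowthFit",
    "TimestampObservation",
    "GrowthDomainError",
    "InsufficientDataError",
    "InconsistentStampsError",
    "volume_index",
    "fit_growth",
    "calibrate_from_timestamps",
]


class GrowthDomainError(ValueError):
    """Requested a radius at a time before the extrapolated nucleation."""


class InsufficientDataError(ValueError):
    """Too few samples/timestamps for the requested fit."""


class InconsistentStampsError(ValueError):
    """Timestamp radii are not increasing with time (growth violated)."""


@dataclass(frozen=True)
class GrowthModel:
    """Constants of the cube-root growth law ``r = (K t + A)^(1/3)``.

    Parameters
    ----------
    K
        Volumetric growth rate, radius-units^3 per hour. Must be > 0.
    A
        Cubed radius at ``t = 0`` (radius-units^3).  Normally >= 0; a
        negative value denotes extrapolated nucleation after ``t = 0``
        (the model is then only valid for ``K t + A >= 0``).
    units
        Free-text label for the radius unit (pixels, micrometres, ...).
    """

    K: float
    A: float = 0.0
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"growth rate K must be positive, got {self.K}")

    def radius_at_time(self, t):
        """Radius at time ``t`` (hours). Raises on negative radicand."""
        t = np.asarray(t, dtype=float)
        radicand = self.K * t + self.A
        if np.any(radicand < 0):
            raise GrowthDomainError(
                "time precedes extrapolated nucleation (K*t + A < 0)"
            )
        r = np.cbrt(radicand)
        return float(r) if r.ndim == 0 else r

    def time_at_radius(self, r):
        """Deposition time of the layer at radius ``r``.

        The exact inverse of :meth:`radius_at_time`.  Negative results are
        permitted and signal deposition before ``t = 0`` (pre-window).
        """
        r = np.asarray(r, dtype=float)
        t = (r**3 - self.A) / self.K
        return float(t) if t.ndim == 0 else t

    def to_json(self) -> str:
        return json.dumps({"K": self.K, "A": self.A, "units": self.units})

    @classmethod
    def from_json(cls, payload: str) -> "GrowthModel":
        d = json.loads(payload)
        return cls(K=float(d["K"]), A=float(d["A"]), units=d.get("units", "arbitrary"))


def volume_index(projected_area):
    """Volume index ``area^(3/2)`` of a projected particle area.

    Proportional to particle volume when growth preserves shape, hence
    linear in time under the constant-volumetric-rate model.
    """
    a = np.asarray(projected_area, dtype=float)
    if np.any(a < 0):
        raise ValueError("projected area must be non-negative")
    v = a**1.5
    return float(v) if v.ndim == 0 else v


@dataclass
class GrowthTrajectory:
    """Time series of particle size, on the radius or volume-index scale."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "volume_index"  # "radius" | "volume_index"
    particle_id: str | int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("radius", "volume_index"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("radii / volume indices must be non-negative")

    def linearized(self) -> np.ndarray:
        """Samples on the cubed-radius scale (linear in time under the model)."""
        return self.values**3 if self.kind == "radius" else self.values.copy()

    def to_frame(self) -> pd.DataFrame:
        col = "radius" if self.kind == "radius" else "volume_index"
        return pd.DataFrame(
            {"particle_id": self.particle_id, "t_h": self.times, col: self.values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, particle_id=None) -> "GrowthTrajectory":
        if particle_id is not None:
            df = df[df["particle_id"] == particle_id]
        kind = "radius" if "radius" in df.columns else "volume_index"
        return cls(
            times=df["t_h"].to_numpy(),
            values=df[kind].to_numpy(),
            kind=kind,
            particle_id=df["particle_id"].iloc[0] if len(df) else 0,
        )


@dataclass
class GrowthFit:
    """Result of a linearized growth fit: slope K, intercept A, R^2."""

    K: float
    A: float
    r_squared: float
    degenerate: bool = False
    units: str = "arbitrary"

    @property
    def model(self) -> GrowthModel:
        if self.degenerate:
            raise ValueError("degenerate fit (non-positive K) has no growth model")
        return GrowthModel(K=self.K, A=self.A, units=self.units)


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = K t + A; returns (K, A, R^2)."""
    X = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), float(coef[1]), r2


def fit_growth(trajectory: GrowthTrajectory, min_samples: int = 3) -> GrowthFit:
    """Fit the cube-root growth law on the linearized scale.

    Cubed radius (or volume index, proportional to it up to a shape
    constant) is regressed linearly on time; the slope estimates ``K`` and
    the intercept ``A``.  ``R^2`` is reported on this linearized scale.

    A non-positive fitted slope is flagged ``degenerate`` (constant or
    shrinking trajectory) rather than raised.
    """
    if len(trajectory.times) < min_samples:
        raise InsufficientDataError(
            f"need at least {min_samples} samples, got {len(trajectory.times)}"
        )
    K, A, r2 = _line_fit(trajectory.times, trajectory.linearized())
    return GrowthFit(K=K, A=A, r_squared=r2, degenerate=not K > 0)


@dataclass(frozen=True)
class TimestampObservation:
    """A known administration time paired with its measured band radius.

    ``mode`` records how the band marks time: a dye *switch* is localized
    by the band onset, a transient *pulse* by the band peak.
    """

    time: float
    radius: float
    mode: str = "switch"  # "switch" | "pulse"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("timestamp band radius must be positive")


def calibrate_from_timestamps(
    stamps: Sequence[TimestampObservation], units: str = "arbitrary"
) -> GrowthModel:
    """Per-particle growth model from timestamp (time, radius) pairs.

    With exactly two stamps the 2x2 linear system on cubed radii is solved
    exactly (``K = (r2^3 - r1^3)/(t2 - t1)``, ``A = r1^3 - K t1``); with
    more, ordinary least squares on cubed radii versus time.
    """
    if len(stamps) < 2:
        raise InsufficientDataError("at least 2 timestamps required")
    order = np.argsort([s.time for s in stamps])
    t = np.array([stamps[i].time for i in order], dtype=float)
    r = np.array([stamps[i].radius for i in order], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InsufficientDataError("timestamp times must be distinct")
    if np.any(np.diff(r) <= 0):
        raise InconsistentStampsError(
            "band radii do not increase with time; particle violates growth"
        )
    y = r**3
    if len(stamps) == 2:
        K = (y[1] - y[0]) / (t[1] - t[0])
        A = y[0] - K * t[0]
    else:
        K, A, _ = _line_fit(t, y)
    if not K > 0:
        raise InconsistentStampsError("calibrated growth rate is non-positive")
    return GrowthModel(K=float(K), A=float(A), units=units)
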