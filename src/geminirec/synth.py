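"""Forward simulator for granular recorder particles.

The simulator turns a recording protocol (dye-switch schedule, pulse
timestamps, stimulus trace) plus per-particle growth parameters into:

* ideal multichannel radial records (deposition map, no optics),
* rendered midplane images and growing-particle timelapse stacks with a
  Gaussian PSF, Poisson shot noise, Gaussian read noise and background,
* fast profile-level Monte-Carlo band sets with Gaussian band-
  localization jitter (no rendering), used for decoding benchmarks,
* noisy growth trajectories for growth-law fitting.

Every stochastic entry point takes an explicit ``seed`` and is bit-
reproducible.  Times are hours; image lengths are pixels unless a
``pixel_size`` converts them.

The midplane silhouette of an octahedral particle growing by uniform
facet addition is drawn as nested square (diamond) level sets: the layer
coordinate of a pixel is the L1 distance from the centre in the
particle's rotated frame, so the outermost level set equals the current
radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .growth import GrowthModel, GrowthTrajectory, volume_index
from .profiles import RadialProfile

__all__ = [
    "DyeSchedule",
    "SignalTrace",
    "ParticleSpec",
    "NoiseModel",
    "MultichannelImage",
    "reporter_concentration",
    "compose_radial_record",
    "render_midplane",
    "render_timelapse",
    "jittered_band_set",
    "timing_jitter_sigma",
    "simulate_growth_trajectories",
]

BOOST_TAU = 0.1  # hours; fast-turnover (destabilized reporter) kinetics


@dataclass
class DyeSchedule:
    """Timestamp dye schedule: permanent switches and transient pulses.

    ``switches`` are (time_h, channel) pairs: from that time on, newly
    deposited layers carry the given label (until the next switch).
    ``pulses`` are (time_h, width_h, channel): the layer deposited within
    ``width/2`` of the pulse time carries the label — a narrow band whose
    intensity maximum coincides with the administration time.
    With ``dark_core`` (default) layers deposited before the first switch
    are non-fluorescent in every stamp channel, producing the dim core
    that marks pre-recording growth.
    """

    switches: list[tuple[float, str]]
    pulses: list[tuple[float, float, str]] = field(default_factory=list)
    dark_core: bool = True

    def __post_init__(self) -> None:
        if not self.switches and not self.pulses:
            raise ValueError("schedule must contain at least one switch or pulse")
        times = [t for t, _ in self.switches]
        if np.any(np.diff(times) <= 0):
            raise ValueError("switch times must be strictly increasing")
        for t, w, _ in self.pulses:
            if not w > 0:
                raise ValueError("pulse width must be positive")

    @property
    def stamp_channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, ch in self.switches:
            seen.setdefault(ch)
        for _, _, ch in self.pulses:
            seen.setdefault(ch)
        return list(seen)


@dataclass
class SignalTrace:
    """Cytoplasmic reporter level versus time, as a kinetic response.

    Each stimulus event (on, off, amplitude) drives a first-order
    response: after ``on + delay`` the concentration rises toward the
    amplitude with time constant ``tau_on``; after ``off + delay`` it
    decays with ``tau_off``.  Events superpose additively on a basal
    level.  ``delay`` models transcription/translation/transport lag
    (default 2 h, the observed reporter lag to stimulation).  ``boost``
    selects fast-turnover kinetics (destabilized reporter and transcript):
    ``tau_on = tau_off = 0.1 h``.
    """

    events: list[tuple[float, float, float]] = field(default_factory=list)
    delay: float = 2.0
    tau_on: float = 0.5
    tau_off: float = 1.0
    basal: float = 0.0
    boost: bool = False

    def __post_init__(self) -> None:
        if self.boost:
            self.tau_on = BOOST_TAU
            self.tau_off = BOOST_TAU
        if self.tau_on < 0 or self.tau_off <= 0:
            raise ValueError("time constants must be positive (tau_on may be 0)")
        for on, off, amp in self.events:
            if not on < off:
                raise ValueError(f"event must have on < off, got ({on}, {off})")
            if amp < 0:
                raise ValueError("event amplitude must be non-negative")

    def concentration(self, t):
        return reporter_concentration(self, t)


def reporter_concentration(trace: SignalTrace, t):
    """Reporter concentration at time(s) ``t`` (relative units).

    Piecewise first-order response per event, additive superposition,
    plus the basal level.  The ``tau_on -> 0`` limit is an instantaneous
    step to the amplitude at ``on + delay``.
    """
    t = np.asarray(t, dtype=float)
    c = np.full(t.shape, float(trace.basal))
    for on, off, amp in trace.events:
        on_, off_ = on + trace.delay, off + trace.delay
        if trace.tau_on > 0:
            rise = amp * (1.0 - np.exp(-np.clip(t - on_, 0, None) / trace.tau_on))
            c_off = amp * (1.0 - np.exp(-(off_ - on_) / trace.tau_on))
        else:
            rise = np.where(t >= on_, amp, 0.0)
            c_off = amp
        decay = c_off * np.exp(-np.clip(t - off_, 0, None) / trace.tau_off)
        c += np.where(t < on_, 0.0, np.where(t < off_, rise, decay))
    return float(c) if c.ndim == 0 else c


@dataclass
class ParticleSpec:
    """Geometry and growth of one simulated particle.

    ``model`` runs on the particle's own clock (time since nucleation);
    ``nucleation_time`` places that clock on the protocol's absolute time
    axis (negative = nucleated before protocol t=0, giving a dark core).
    """

    model: GrowthModel
    centre: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    nucleation_time: float = 0.0
    particle_id: str | int = 0

    def radius_at(self, t):
        """Particle radius at absolute time ``t`` (0 before nucleation)."""
        t = np.asarray(t, dtype=float)
        age = np.clip(t - self.nucleation_time, 0.0, None)
        r = np.cbrt(self.model.K * age + np.clip(self.model.A, 0.0, None))
        r = np.where(t < self.nucleation_time, 0.0, r)
        return float(r) if r.ndim == 0 else r

    def deposition_time(self, ell):
        """Absolute time at which the layer at radius ``ell`` was deposited."""
        ell = np.asarray(ell, dtype=float)
        t = self.nucleation_time + self.model.time_at_radius(ell)
        return float(t) if t.ndim == 0 else t


@dataclass
class NoiseModel:
    """Optical and measurement noise for rendering and profile jitter.

    ``psf_sigma`` — Gaussian point-spread sigma (length units).
    ``shot_noise`` — photons per intensity unit for Poisson shot noise
    (0 disables).  ``read_noise_sd`` — additive Gaussian read noise.
    ``background`` — constant offset added before shot noise.
    ``radial_jitter_sd`` — band-localization error (radius units) used by
    the profile-level Monte-Carlo.
    """

    psf_sigma: float = 1.0
    shot_noise: float = 0.0
    read_noise_sd: float = 0.0
    background: float = 0.0
    radial_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("psf_sigma", "shot_noise", "read_noise_sd", "background",
                     "radial_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class MultichannelImage(NamedTuple):
    """A (C, H, W) image with channel names and provenance metadata."""

    data: np.ndarray
    channels: list[str]
    meta: dict


def compose_radial_record(
    spec: ParticleSpec,
    schedule: DyeSchedule,
    trace: SignalTrace | None = None,
    end_time: float = 0.0,
    resolution: float = 0.25,
    signal_channel: str = "signal",
    gain: float = 1.0,
    c_ref: float | None = None,
) -> RadialProfile:
    """Ideal (optics-free) multichannel radial record of one particle.

    For every layer radius ``ell`` up to the radius at ``end_time``
    (fixation), the deposition time is obtained from the growth model;
    switch channels carry the dye active at that time, pulse channels a
    centred top-hat of the pulse width, and the signal channel an
    intensity proportional to the reporter concentration at deposition
    (``gain * c / c_ref``; ``c_ref`` defaults to the maximum realized
    concentration).  Layers deposited before the first switch are dark in
    all stamp channels.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    r_end = spec.radius_at(end_time)
    if r_end <= resolution:
        raise ValueError("particle has not grown beyond one layer by end_time")
    ell = np.arange(0.0, r_end + 0.5 * resolution, resolution)
    ell[0] = min(resolution * 1e-3, ell[1] * 0.5)  # avoid ell=0 degeneracy
    t_dep = spec.deposition_time(ell)

    channels: dict[str, np.ndarray] = {
        ch: np.zeros_like(ell) for ch in schedule.stamp_channels
    }
    if schedule.switches:
        sw_times = np.array([t for t, _ in schedule.switches])
        idx = np.searchsorted(sw_times, t_dep, side="right") - 1
        for i, (_, ch) in enumerate(schedule.switches):
            channels[ch][idx == i] = 1.0
        if not schedule.dark_core:
            # pre-switch layers carry the first label instead of staying dark
            channels[schedule.switches[0][1]][idx < 0] = 1.0
    for pt, w, ch in schedule.pulses:
        channels[ch][np.abs(t_dep - pt) <= 0.5 * w] += 1.0

    if trace is not None:
        c = reporter_concentration(trace, t_dep)
        ref = c_ref if c_ref is not None else (float(np.max(c)) or 1.0)
        channels[signal_channel] = gain * c / ref

    meta = {
        "particle_id": spec.particle_id,
        "end_time": end_time,
        "resolution": resolution,
        "r_end": float(r_end),
        "ideal": True,
    }
    return RadialProfile(ell=ell, channels=channels, meta=meta)


def _l1_layer_map(shape, centre, orientation, pixel_size):
    """Layer coordinate (length units) of every pixel for one particle."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - centre[0]) * pixel_size
    dy = (yy - centre[1]) * pixel_size
    c, s = np.cos(orientation), np.sin(orientation)
    xr = dx * c + dy * s
    yr = -dx * s + dy * c
    return np.abs(xr) + np.abs(yr)


def _apply_noise(img: np.ndarray, noise: NoiseModel, pixel_size: float, rng):
    img = img + noise.background
    if noise.psf_sigma > 0:
        sigma_px = noise.psf_sigma / pixel_size
        for c in range(img.shape[0]):
            img[c] = ndimage.gaussian_filter(img[c], sigma_px)
    if noise.shot_noise > 0:
        img = rng.poisson(np.clip(img, 0, None) * noise.shot_noise) / noise.shot_noise
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    return img


def render_midplane(
    records: Sequence[tuple[ParticleSpec, RadialProfile]],
    image_shape: tuple[int, int],
    pixel_size: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> MultichannelImage:
    """Render particle midplane cross-sections into a multichannel image.

    Each particle is drawn as nested square (diamond) level sets: the
    pixel's layer coordinate is the L1 distance from the particle centre
    in its rotated frame (scaled by ``pixel_size``), and the per-channel
    intensity is the radial record interpolated at that coordinate (zero
    outside the outermost layer).  PSF blur, shot noise, read noise and
    background follow if a :class:`NoiseModel` is given (then ``seed`` is
    required when stochastic terms are enabled).  Overlapping particles
    are allowed but flagged in ``meta["overlap"]``.
    """
    noise = noise or NoiseModel(psf_sigma=0.0)
    stochastic = noise.shot_noise > 0 or noise.read_noise_sd > 0
    if stochastic and seed is None:
        raise ValueError("seed is required when shot/read noise is enabled")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    for _, rec in records:
        for ch in rec.channels:
            if ch not in names:
                names.append(ch)
    h, w = image_shape
    img = np.zeros((len(names), h, w))
    coverage = np.zeros((h, w), dtype=int)
    for spec, rec in records:
        ell_map = _l1_layer_map(image_shape, spec.centre, spec.orientation, pixel_size)
        r_max = float(rec.ell[-1])
        inside = ell_map <= r_max
        coverage += inside
        for ci, ch in enumerate(names):
            if ch not in rec.channels:
                continue
            vals = np.interp(
                ell_map[inside], rec.ell, rec.channels[ch],
                left=rec.channels[ch][0], right=0.0,
            )
            img[ci][inside] += vals
    img = _apply_noise(img, noise, pixel_size, rng)
    meta = {
        "pixel_size": pixel_size,
        "seed": seed,
        "overlap": bool((coverage > 1).any()),
        "n_particles": len(records),
    }
    return MultichannelImage(data=img, channels=names, meta=meta)


def render_timelapse(
    specs: Sequence[ParticleSpec],
    frame_times: Sequence[float],
    image_shape: tuple[int, int],
    pixel_size: float = 1.0,
    intensity: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Growing-particle timelapse stack plus a ground-truth track table.

    Particles are rendered with uniform interior intensity (the total
    assembly channel used for tracking); sizes follow each particle's
    growth model.  The ground-truth table has one row per visible
    particle per frame: frame, t_h, particle_id, x, y, radius_px,
    area_px (= 2 r^2 for the square silhouette).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    noise = noise or NoiseModel(psf_sigma=0.0)
    stochastic = noise.shot_noise > 0 or noise.read_noise_sd > 0
    if stochastic and seed is None:
        raise ValueError("seed is required when shot/read noise is enabled")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    stack = np.zeros((len(frame_times), h, w))
    rows = []
    layer_maps = [
        _l1_layer_map(image_shape, s.centre, s.orientation, pixel_size) for s in specs
    ]
    for fi, t in enumerate(frame_times):
        frame = np.zeros((1, h, w))
        for spec, ell_map in zip(specs, layer_maps):
            r = spec.radius_at(t)
            if r <= 0:
                continue
            frame[0][ell_map <= r] += intensity
            r_px = r / pixel_size
            rows.append(
                {
                    "frame": fi,
                    "t_h": float(t),
                    "particle_id": spec.particle_id,
                    "x": spec.centre[0],
                    "y": spec.centre[1],
                    "radius_px": r_px,
                    "area_px": 2.0 * r_px**2,
                }
            )
        stack[fi] = _apply_noise(frame, noise, pixel_size, rng)[0]
    return stack, pd.DataFrame(rows)


def _draw_growth_rates(n: int, k_mean: float, k_cv: float, rng) -> np.ndarray:
    """Per-particle volumetric rates: log-normal with the given mean and CV."""
    if k_cv <= 0:
        return np.full(n, k_mean)
    s2 = np.log1p(k_cv**2)
    mu = np.log(k_mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), size=n)


def timing_jitter_sigma(
    k: float,
    nucleation_time: float,
    stamp_times: tuple[float, float],
    sigma_t: float,
    at_time: float | None = None,
) -> float:
    """Radial jitter s.d. giving a target decoded timing s.d.

    Delta-method error propagation through two-timestamp decoding: with
    independent Gaussian radial jitter ``sigma_r`` on the two stamp bands
    and the signal band, the decoded-time variance at signal time ``ts``
    is ``9 sigma_r^2 [r_s^4 + r_1^4 ((ts-T2)/(T2-T1))^2 +
    r_2^4 ((ts-T1)/(T2-T1))^2] / K^2``.  The returned ``sigma_r`` makes
    the TOTAL decoded s.d. equal ``sigma_t`` at ``at_time`` (default: the
    midpoint of the stamp window).  The single-band special case reduces
    to ``sigma_r = K sigma_t / (3 r^2)``.
    """
    t1, t2 = stamp_times
    ts = 0.5 * (t1 + t2) if at_time is None else at_time

    def r(t):
        return (k * (t - nucleation_time)) ** (1.0 / 3.0)

    span = t2 - t1
    amp = 9.0 * (
        r(ts) ** 4
        + r(t1) ** 4 * ((ts - t2) / span) ** 2
        + r(t2) ** 4 * ((ts - t1) / span) ** 2
    ) / k**2
    return sigma_t / np.sqrt(amp)


def jittered_band_set(
    stamp_times: Sequence[float],
    event_times: Sequence[float],
    n_particles: int,
    radial_jitter_sd: float,
    k_mean: float = 0.3,
    k_cv: float = 0.2,
    nucleation_time: float = -8.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Profile-level Monte-Carlo: observed band radii without rendering.

    Per particle, a growth rate is drawn (log-normal, CV ``k_cv``), ideal
    band radii are computed for every stamp and event time, and
    independent Gaussian radial jitter of s.d. ``radial_jitter_sd`` is
    added.  Columns: particle, role (stamp|event), time, radius_true,
    radius_obs, K.  Reproducible by ``seed``.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    ks = _draw_growth_rates(n_particles, k_mean, k_cv, rng)
    stamp_times = np.asarray(stamp_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    all_times = np.concatenate([stamp_times, event_times])
    roles = ["stamp"] * len(stamp_times) + ["event"] * len(event_times)
    rows = []
    for p in range(n_particles):
        ages = all_times - nucleation_time
        r_true = np.cbrt(ks[p] * ages)
        r_obs = r_true + rng.normal(0.0, radial_jitter_sd, size=r_true.shape)
        for role, t, rt, ro in zip(roles, all_times, r_true, r_obs):
            rows.append(
                {
                    "particle": p,
                    "role": role,
                    "time": float(t),
                    "radius_true": float(rt),
                    "radius_obs": float(ro),
                    "K": float(ks[p]),
                }
            )
    return pd.DataFrame(rows)


def simulate_growth_trajectories(
    n_particles: int = 35,
    duration: float = 48.0,
    dt: float = 0.5,
    k_mean: float = 0.3,
    k_cv: float = 0.2,
    subunit_volume: float = 2.7e-5,
    area_noise_sd: float = 0.02,
    shape_factor: float = 2.0,
    seed: int | None = None,
) -> tuple[list[GrowthTrajectory], pd.DataFrame]:
    """Noisy volume-index growth trajectories for growth-law fitting.

    Subunit addition is a Poisson counting process (rate ``K / v`` per
    hour with ``v`` the effective per-cage lattice volume, default
    (30 nm)^3 in um^3), so particle volume carries intrinsic shot noise
    on top of which a multiplicative area measurement error (s.d.
    ``area_noise_sd``) is applied.  Projected area = ``shape_factor *
    r^2`` (2 for the square midplane).  Returns per-particle
    volume-index trajectories and a ground-truth table of drawn rates.
    """
    rng = np.random.default_rng(seed)
    ks = _draw_growth_rates(n_particles, k_mean, k_cv, rng)
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    trajectories = []
    for p in range(n_particles):
        increments = rng.poisson(ks[p] * dt / subunit_volume, size=len(times) - 1)
        volume = np.concatenate([[0.0], np.cumsum(increments)]) * subunit_volume
        r = np.cbrt(volume)
        area = shape_factor * r**2
        area_obs = area * (1.0 + rng.normal(0.0, area_noise_sd, size=area.shape))
        vi = volume_index(np.clip(area_obs, 0.0, None))
        trajectories.append(
            GrowthTrajectory(times=times, values=vi, kind="volume_index", particle_id=p)
        )
    truth = pd.DataFrame({"particle_id": np.arange(n_particles), "K": ks})
    return trajectories, truth
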