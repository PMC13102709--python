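"""Particle detection and single-particle tracking.

Detection enhances particle boundaries with adaptive thresholding OR'd
with a Sobel gradient mask, fills the resulting regions, locates centres
as maxima of the distance transform, and measures per-region centroid,
area and mean intensity; a radius estimate is taken from the largest
radial extent still above an intensity cut-off over background.

Tracking links detections across a timelapse frame by frame in reverse
chronological order (so track ends in processing order correspond to
nucleation in forward time) by minimizing a linear-sum-assignment cost
combining distance, area difference and intensity difference.  Tracks
showing likely errors (gaps, non-monotone area, short length) are flagged
for exclusion rather than repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import sobel, threshold_local
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .growth import GrowthTrajectory, volume_index

__all__ = [
    "Detection",
    "TrackerConfig",
    "ParticleTrack",
    "detect_particles",
    "link_tracks",
    "track_to_growth",
    "qc_tracks",
    "tracks_to_frame",
]

_FORBIDDEN = 1e9  # cost assigned to links beyond the gating distance


@dataclass(frozen=True)
class Detection:
    """One particle found in one frame."""

    frame_index: int
    x: float
    y: float
    area: float
    mean_intensity: float
    radius_estimate: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("detection area must be positive")


@dataclass
class TrackerConfig:
    """Detection and linking parameters.

    Linking: ``d_max`` gates candidate links (pixels); ``w_area`` and
    ``w_intensity`` weight the relative area/intensity difference terms of
    the assignment cost (distance is normalized by ``d_max`` so all terms
    live on [0, 1]).

    Detection: ``adaptive_block`` sets the local-mean window and
    ``adaptive_offset`` the threshold margin above the local mean, as a
    fraction of the frame's dynamic range; ``sobel_threshold`` the
    gradient mask (None = 4x the median gradient magnitude),
    ``min_separation`` the minimum spacing of distance-transform maxima,
    ``cutoff_fraction`` and ``background`` the radius estimate,
    ``min_area`` suppresses speckle regions, and ``min_snr`` rejects
    regions whose peak does not exceed the frame median by that many
    robust (MAD-based) noise standard deviations.
    """

    d_max: float = 30.0
    w_area: float = 1.0
    w_intensity: float = 1.0
    adaptive_block: int = 51
    adaptive_offset: float = 0.02
    sobel_threshold: float | None = None
    min_separation: int = 10
    cutoff_fraction: float = 0.5
    background: float = 0.0
    min_area: int = 20
    min_snr: float = 5.0
    bridge_gaps: bool = False  # optional 1-frame gap bridging

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if self.w_area < 0 or self.w_intensity < 0:
            raise ValueError("cost weights must be non-negative")
        if self.adaptive_block % 2 == 0:
            raise ValueError("adaptive_block must be odd")


@dataclass
class ParticleTrack:
    """Detections of one particle linked across frames (forward order)."""

    track_id: int
    detections: list[Detection]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if len(set(frames)) != len(frames):
            raise ValueError("at most one detection per frame")
        if frames != sorted(frames):
            raise ValueError("detections must be in increasing frame order")

    @property
    def frames(self) -> list[int]:
        return [d.frame_index for d in self.detections]

    @property
    def n_gaps(self) -> int:
        f = self.frames
        return int(sum(b - a - 1 for a, b in zip(f, f[1:])))


def _radius_estimate(region, frame, centre, cutoff_fraction, background) -> float:
    """Largest radial extent where intensity >= cutoff above background."""
    coords = region.coords  # (row, col)
    intens = frame[coords[:, 0], coords[:, 1]]
    peak = float(intens.max())
    thr = background + cutoff_fraction * (peak - background)
    keep = intens >= thr
    if not keep.any():
        return 0.0
    cx, cy = centre
    d = np.hypot(coords[keep, 1] - cx, coords[keep, 0] - cy)
    return float(d.max())


def detect_particles(frame: np.ndarray, config: TrackerConfig | None = None,
                     frame_index: int = 0) -> list[Detection]:
    """Detect recorder particles in a single 2D frame.

    Pipeline: adaptive (local-mean) threshold OR Sobel gradient mask ->
    hole filling -> small-object removal -> Euclidean distance transform
    -> maxima (minimum separation) as centres -> watershed region
    assignment -> intensity-weighted centroid, area, mean intensity and
    cut-off-based radius estimate per region.

    An empty or featureless frame returns an empty list; a frame with a
    substantial saturated fraction raises a warning.
    """
    config = config or TrackerConfig()
    raw = np.asarray(frame)
    if np.issubdtype(raw.dtype, np.integer):
        dtype_max = np.iinfo(raw.dtype).max
        if np.mean(raw >= dtype_max) > 0.005:
            warnings.warn("frame appears saturated (>0.5% of pixels at dtype max)")
    frame = raw.astype(float)
    if frame.ndim != 2:
        raise ValueError("detect_particles expects a single-channel 2D frame")
    if frame.size == 0 or frame.max() == frame.min():
        return []

    local_mean = threshold_local(
        frame, block_size=config.adaptive_block, method="mean"
    )
    offset = config.adaptive_offset * (frame.max() - frame.min())
    mask = frame > local_mean + offset
    grad = sobel(frame)
    sob_thr = (
        config.sobel_threshold
        if config.sobel_threshold is not None
        else 4.0 * float(np.median(grad))
    )
    if sob_thr > 0:
        mask |= grad > sob_thr
    mask = ndimage.binary_fill_holes(mask)
    # drop speckle components below the minimum area
    lab, n = ndimage.label(mask)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = np.isin(lab, np.flatnonzero(sizes >= config.min_area) + 1)
    if not mask.any():
        return []

    dist = ndimage.distance_transform_edt(mask)
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        dist, min_distance=config.min_separation, labels=mask, exclude_border=False
    )
    if len(coords) == 0:
        return []
    markers = np.zeros(frame.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=mask)

    med = float(np.median(frame))
    noise_sd = 1.4826 * float(np.median(np.abs(frame - med)))
    intensity_floor = med + config.min_snr * noise_sd

    detections = []
    for region in regionprops(labels, intensity_image=frame):
        if region.area < config.min_area:
            continue
        if region.intensity_max < intensity_floor:
            continue
        cy, cx = region.centroid_weighted
        if not (np.isfinite(cx) and np.isfinite(cy)):
            cy, cx = region.centroid  # zero-intensity region: geometric centroid
        detections.append(
            Detection(
                frame_index=frame_index,
                x=float(cx),
                y=float(cy),
                area=float(region.area),
                mean_intensity=float(region.intensity_mean),
                radius_estimate=_radius_estimate(
                    region, frame, (cx, cy), config.cutoff_fraction, config.background
                ),
            )
        )
    return detections


def link_cost_matrix(
    a: Sequence[Detection], b: Sequence[Detection], config: TrackerConfig
) -> np.ndarray:
    """Pairwise linking cost between two detection sets.

    ``c_ij = d_ij/d_max + w_A |A_i - A_j| / max(A_i, A_j)
            + w_I |I_i - I_j| / max(I_i, I_j)``;
    pairs beyond ``d_max`` get a forbidding cost.
    """
    cost = np.zeros((len(a), len(b)))
    for i, da in enumerate(a):
        for j, db in enumerate(b):
            d = np.hypot(da.x - db.x, da.y - db.y)
            if d > config.d_max:
                cost[i, j] = _FORBIDDEN
                continue
            c = d / config.d_max
            amax = max(da.area, db.area)
            if amax > 0:
                c += config.w_area * abs(da.area - db.area) / amax
            imax = max(abs(da.mean_intensity), abs(db.mean_intensity))
            if imax > 0:
                c += config.w_intensity * abs(da.mean_intensity - db.mean_intensity) / imax
            cost[i, j] = c
    return cost


def solve_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Optimal assignment on a (possibly rectangular) cost matrix.

    Linear-sum-assignment (Hungarian) solution; pairs carrying the
    forbidding cost are dropped from the result.
    """
    if cost.size == 0:
        return []
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _FORBIDDEN]


def brute_force_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Exhaustive-permutation assignment oracle for small instances."""
    n, m = cost.shape
    if n * m == 0:
        return []
    if n > 8 or m > 8:
        raise ValueError("brute force limited to 8x8 instances")
    transposed = n > m
    c = cost.T if transposed else cost
    best, best_perm = np.inf, None
    for perm in permutations(range(c.shape[1]), c.shape[0]):
        total = sum(c[i, p] for i, p in enumerate(perm))
        if total < best:
            best, best_perm = total, perm
    pairs = [(i, p) for i, p in enumerate(best_perm) if c[i, p] < _FORBIDDEN]
    return [(j, i) for i, j in pairs] if transposed else pairs


def link_tracks(
    detections_per_frame: Sequence[Sequence[Detection]],
    config: TrackerConfig | None = None,
    reverse: bool = True,
) -> list[ParticleTrack]:
    """Link per-frame detections into particle tracks.

    Frames are processed in reverse chronological order (default,
    matching the recorder's growth geometry: every particle is present
    and largest in the last frame, and an unmatched earlier-frame head
    marks its nucleation).  ``reverse=False`` processes forward instead;
    on gap-free well-separated scenes both orders give identical tracks.
    """
    config = config or TrackerConfig()
    n_frames = len(detections_per_frame)
    if n_frames < 2:
        raise ValueError("need at least 2 frames to link")
    order = range(n_frames - 1, -1, -1) if reverse else range(n_frames)
    it = iter(order)
    first = next(it)
    # active: list of (detections in processing order, misses)
    active = [[[d], 0] for d in detections_per_frame[first]]
    finished: list[list[Detection]] = []
    for f in it:
        dets = list(detections_per_frame[f])
        heads = [tr[0][-1] for tr in active]
        cost = link_cost_matrix(heads, dets, config)
        pairs = solve_assignment(cost) if len(heads) and len(dets) else []
        matched_heads = {i for i, _ in pairs}
        matched_dets = {j for _, j in pairs}
        next_active = []
        for i, j in pairs:
            active[i][0].append(dets[j])
            active[i][1] = 0
            next_active.append(active[i])
        for i, tr in enumerate(active):
            if i in matched_heads:
                continue
            if config.bridge_gaps and tr[1] < 1:
                tr[1] += 1
                next_active.append(tr)  # keep alive across one missed frame
            else:
                finished.append(tr[0])
        for j, d in enumerate(dets):
            if j not in matched_dets:
                next_active.append([[d], 0])
        active = next_active
    finished.extend(tr[0] for tr in active)

    tracks = []
    for tid, dets in enumerate(finished):
        ordered = dets[::-1] if reverse else dets
        tracks.append(ParticleTrack(track_id=tid, detections=ordered))
    tracks.sort(key=lambda t: (t.frames[0], t.detections[0].x, t.detections[0].y))
    for tid, t in enumerate(tracks):
        t.track_id = tid
    return tracks


def track_to_growth(
    track: ParticleTrack,
    frame_times: Sequence[float],
    normalize: bool = False,
) -> GrowthTrajectory:
    """Convert a track's areas into a volume-index growth trajectory.

    Emits ``(t, area^(3/2))`` samples; with ``normalize`` the index is
    divided by its final value so growth rates of different particles can
    be compared directly.
    """
    if not track.detections:
        raise ValueError("track is empty")
    frame_times = np.asarray(frame_times, dtype=float)
    t = frame_times[track.frames]
    vi = volume_index(np.array([d.area for d in track.detections]))
    vi = np.atleast_1d(vi)
    if normalize and vi[-1] > 0:
        vi = vi / vi[-1]
    return GrowthTrajectory(times=t, values=vi, kind="volume_index",
                            particle_id=track.track_id)


def qc_tracks(
    tracks: Sequence[ParticleTrack],
    min_length: int = 5,
    max_gaps: int = 0,
    area_drop_tolerance: float = 0.3,
) -> list[ParticleTrack]:
    """Flag tracks showing likely tracking errors.

    Flags: ``short`` (below ``min_length`` frames), ``gaps`` (more missed
    frames than allowed), ``non_monotone_area`` (area falls more than the
    tolerated fraction below its running maximum — growth never shrinks a
    particle, so this indicates mislinking).  Flagged tracks are returned,
    not removed; exclusion is the caller's decision.
    """
    out = []
    for tr in tracks:
        flags = list(tr.flags)
        if len(tr.detections) < min_length:
            flags.append("short")
        if tr.n_gaps > max_gaps:
            flags.append("gaps")
        areas = np.array([d.area for d in tr.detections])
        if len(areas) >= 2:
            running_max = np.maximum.accumulate(areas)
            if np.any(areas < (1.0 - area_drop_tolerance) * running_max):
                flags.append("non_monotone_area")
        out.append(ParticleTrack(track_id=tr.track_id,
                                 detections=list(tr.detections),
                                 flags=sorted(set(flags))))
    return out


def tracks_to_frame(
    tracks: Sequence[ParticleTrack], frame_times: Sequence[float] | None = None
) -> pd.DataFrame:
    """Tabulate tracks: one row per detection with track id and flags."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": d.frame_index,
                    "t_h": (
                        float(frame_times[d.frame_index])
                        if frame_times is not None
                        else np.nan
                    ),
                    "x": d.x,
                    "y": d.y,
                    "area_px": d.area,
                    "mean_intensity": d.mean_intensity,
                    "radius_px": d.radius_estimate,
                    "volume_index": float(d.area) ** 1.5,
                    "flags": ";".join(tr.flags),
                }
            )
    return pd.DataFrame(rows)
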