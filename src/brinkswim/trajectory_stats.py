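"""Cell-trajectory and tracer-dispersal statistics.

Mean speed, segmentwise tortuosity, time-and-ensemble-averaged MSD with
its power-law exponent, per-track maximum displacement over a fixed lag,
and the radius of influence of a swimmer's path on the surrounding
tracers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TracerSet",
    "mean_speed",
    "tortuosity",
    "msd",
    "max_displacement_per_track",
    "radius_of_influence",
    "filter_tracks_by_speed",
    "trajectories_from_tracks",
]

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Sampled 2D path: strictly increasing times (s), positions (um)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def speeds(self) -> np.ndarray:
        return self.step_lengths() / np.diff(self.t)


@dataclass
class TracerSet:
    """A bag of tracer trajectories sharing one frame rate."""

    tracks: list[Trajectory]
    frame_rate: float = 500.0

    def __len__(self) -> int:
        return len(self.tracks)


def filter_tracks_by_speed(tracks: TracerSet, min_speed: float = 1.0) -> TracerSet:
    """Keep only tracks whose mean speed exceeds ``min_speed`` um/s
    (mirrors the inclusion rule used for the motility statistics)."""
    kept = [tr for tr in tracks.tracks if len(tr) >= 2 and mean_speed(tr) > min_speed]
    return TracerSet(kept, tracks.frame_rate)


def trajectories_from_tracks(tracks: pd.DataFrame, frame_rate: float = 500.0) -> TracerSet:
    """Group a track table (track_id, t_s, x_um, y_um) into a TracerSet."""
    out = []
    for _, g in tracks.groupby("track_id", sort=False):
        g = g.sort_values("t_s")
        out.append(Trajectory(g["t_s"].to_numpy(), g["x_um"].to_numpy(), g["y_um"].to_numpy()))
    return TracerSet(out, frame_rate)


def mean_speed(traj: Trajectory) -> float:
    """Mean frame-to-frame speed in um/s."""
    if len(traj) < 2:
        raise ValueError("mean speed needs at least two samples")
    return float(np.mean(traj.speeds()))


def tortuosity(traj: Trajectory, segment_arclength: float = 20.0) -> float:
    """Mean arclength-over-chord ratio of consecutive 20 um segments.

    The trajectory is cut at exact arclength multiples of
    ``segment_arclength`` (points inserted by linear interpolation); the
    trailing partial segment is dropped and the per-segment ratios are
    averaged.  Straight motion gives 1.
    """
    if len(traj) < 2:
        raise ValueError("tortuosity needs at least two samples")
    steps = traj.step_lengths()
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    n_seg = int(np.floor(total / segment_arclength))
    if n_seg < 1:
        raise ValueError(
            f"trajectory arclength {total:.2f} um shorter than one "
            f"{segment_arclength} um segment"
        )
    # positions at exact arclength boundaries
    bounds = segment_arclength * np.arange(n_seg + 1)
    bx = np.interp(bounds, s, traj.x)
    by = np.interp(bounds, s, traj.y)
    ratios = []
    for k in range(n_seg):
        chord = np.hypot(bx[k + 1] - bx[k], by[k + 1] - by[k])
        ratios.append(np.inf if chord == 0 else segment_arclength / chord)
    return float(np.mean(ratios))


def msd(
    tracks: TracerSet,
    lags: np.ndarray | None = None,
    fit_window: tuple[float, float] = (0.02, 1.0),
    min_tracks: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Time-and-ensemble-averaged MSD and its log-log slope alpha.

    Uses overlapping time origins within each track.  ``lags`` defaults
    to every multiple of the frame interval up to half the shortest
    track.  Returns (lags, msd, alpha) with alpha fitted by least
    squares over ``fit_window`` (s).
    """
    if len(tracks) < min_tracks:
        raise ValueError(f"need at least {min_tracks} tracks")
    dt = 1.0 / tracks.frame_rate
    if lags is None:
        n_min = min(len(tr) for tr in tracks.tracks)
        max_steps = max(n_min // 2, 1)
        steps = np.unique(
            np.rint(np.geomspace(1, max_steps, num=min(40, max_steps))).astype(int)
        )
    else:
        steps = np.unique(np.rint(np.asarray(lags) / dt).astype(int))
        steps = steps[steps >= 1]
    if len(steps) == 0:
        raise ValueError("empty lag window")

    sums = np.zeros(len(steps))
    counts = np.zeros(len(steps), dtype=int)
    for tr in tracks.tracks:
        n = len(tr)
        for si, k in enumerate(steps):
            if k >= n:
                continue
            dx = tr.x[k:] - tr.x[:-k]
            dy = tr.y[k:] - tr.y[:-k]
            sums[si] += np.sum(dx * dx + dy * dy)
            counts[si] += n - k
    ok = counts > 0
    lags_s = steps[ok] * dt
    curve = sums[ok] / counts[ok]

    lo, hi = fit_window
    fit = (lags_s >= lo) & (lags_s <= hi) & (curve > 0)
    if fit.sum() < 2:
        raise ValueError("fit window selects fewer than two lags")
    alpha = float(np.polyfit(np.log(lags_s[fit]), np.log(curve[fit]), 1)[0])
    return lags_s, curve, alpha


def max_displacement_per_track(
    tracks: TracerSet, lag: float = 0.2
) -> tuple[np.ndarray, list[Trajectory]]:
    """Per-track max |r(t + lag) - r(t)| over all start times.

    Tracks shorter than the lag are skipped (count logged).  Returns the
    displacement array and the matching list of retained tracks.
    """
    k = int(round(lag * tracks.frame_rate))
    if k < 1:
        raise ValueError("lag shorter than one frame")
    vals, kept = [], []
    skipped = 0
    for tr in tracks.tracks:
        if len(tr) <= k:
            skipped += 1
            continue
        dx = tr.x[k:] - tr.x[:-k]
        dy = tr.y[k:] - tr.y[:-k]
        vals.append(float(np.max(np.hypot(dx, dy))))
        kept.append(tr)
    if skipped:
        logger.info("max_displacement: skipped %d short tracks", skipped)
    return np.asarray(vals), kept


def radius_of_influence(
    tracks: TracerSet,
    path_point: tuple[float, float],
    path_direction: tuple[float, float],
    threshold: float = 0.2,
    bin_width: float = 5.0,
    lag: float = 0.2,
    min_tracks: int = 20,
) -> float | None:
    """Lateral range over which a swimmer's path advects the tracers.

    Tracks are binned by the perpendicular distance of their mean
    position to the swim path; the statistic per bin is the mean of the
    per-track maximum displacement over ``lag``.  Returns the smallest
    distance (linear interpolation between bin centres) where the bin
    statistic first drops below ``threshold`` times the overall maximum
    bin statistic, or None when it never does.
    """
    dr, kept = max_displacement_per_track(tracks, lag=lag)
    if len(kept) < min_tracks:
        raise ValueError(f"need at least {min_tracks} usable tracks")
    p0 = np.asarray(path_point, dtype=float)
    d = np.asarray(path_direction, dtype=float)
    d = d / np.linalg.norm(d)
    normal = np.array([-d[1], d[0]])
    centres = np.array([[tr.x.mean(), tr.y.mean()] for tr in kept])
    dist = np.abs((centres - p0) @ normal)

    n_bins = int(np.ceil(dist.max() / bin_width)) + 1
    idx = np.minimum((dist / bin_width).astype(int), n_bins - 1)
    stat = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            stat[b] = dr[sel].mean()
    pos = bin_width * (np.arange(n_bins) + 0.5)
    ok = np.isfinite(stat)
    pos, stat = pos[ok], stat[ok]
    cut = threshold * np.nanmax(stat)
    below = np.where(stat < cut)[0]
    if len(below) == 0:
        return None
    b = below[0]
    if b == 0:
        return float(pos[0])
    x1, x2 = pos[b - 1], pos[b]
    y1, y2 = stat[b - 1], stat[b]
    return float(x1 + (y1 - cut) / (y1 - y2) * (x2 - x1))
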