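"""Position preprocessing: track projection, speed, masks, laps, bins.

The 2-D tracking cloud is reduced to a 1-D track coordinate ``s`` (cm) by
projection onto its principal axis.  Instantaneous speed is smoothed with a
Hamming window; analysis is restricted to samples moving faster than the
speed threshold and outside the reward zones at both track ends.  Laps
(end-to-end traversals) are segmented from reward-margin crossings so that
lap geometry and the analysis mask share one definition of "track end".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import AnalysisConfig, DataError, PositionTrace

__all__ = [
    "SpeedTrace",
    "LapSegment",
    "BinGrid",
    "make_grid",
    "bin_index",
    "project_to_track",
    "compute_speed",
    "active_mask",
    "segment_laps",
    "sample_directions",
]


@dataclass
class SpeedTrace:
    """Instantaneous, Hamming-smoothed speed aligned to the position samples."""

    t: np.ndarray
    v: np.ndarray  # cm/s, >= 0


@dataclass(frozen=True)
class LapSegment:
    """One complete end-to-end traversal.

    ``direction`` is +1 for rightward (towards s = L) and -1 for leftward
    runs; ``t_start``/``t_end`` delimit the interval between leaving one
    reward zone and entering the opposite one.
    """

    index: int
    t_start: float
    t_end: float
    direction: int


@dataclass(frozen=True)
class BinGrid:
    """Uniform spatial binning of [0, track_length].

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed, so
    a 170 cm track at 3 cm yields exactly 57 bins.
    """

    bin_cm: float
    n_bins: int
    edges: np.ndarray
    track_length_cm: float

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_cm


def make_grid(track_length_cm: float, bin_cm: float = 3.0) -> BinGrid:
    if track_length_cm <= 0 or bin_cm <= 0:
        raise DataError("track length and bin width must be positive")
    n_bins = math.ceil(track_length_cm / bin_cm)
    edges = np.arange(n_bins + 1, dtype=float) * bin_cm
    return BinGrid(bin_cm=bin_cm, n_bins=n_bins, edges=edges, track_length_cm=track_length_cm)


def bin_index(s, grid: BinGrid):
    """Map track coordinates in [0, L] to 0-based bin ordinals.

    ``s = L`` falls into the last bin (the closed upper edge).
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > grid.track_length_cm):
        raise DataError("coordinate outside [0, track_length]")
    idx = np.minimum(np.floor(s_arr / grid.bin_cm).astype(int), grid.n_bins - 1)
    return idx if s_arr.ndim else int(idx)


def project_to_track(position: PositionTrace, track_length_cm: float) -> np.ndarray:
    """Project 2-D coordinates onto the track's principal axis.

    The centred (x, y) cloud is projected onto its first principal component
    and min-max scaled so the observed extremes map to [0, track_length].
    Orientation is fixed so the first half-track excursion runs low-to-high
    (the first lap runs 0 -> L).
    """
    xy = np.column_stack([position.x, position.y])
    centred = xy - xy.mean(axis=0)
    # principal axis via SVD; degenerate clouds have no direction to project on
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv[0] <= 1e-12:
        raise DataError("degenerate position cloud: zero spatial variance")
    proj = centred @ vt[0]
    span = proj.max() - proj.min()
    if span <= 0:
        raise DataError("degenerate position cloud: zero extent along track")
    s = (proj - proj.min()) / span * track_length_cm
    # orient: find the first excursion of at least half a track away from the
    # starting point; if none exists, use the largest excursion
    dev = np.abs(s - s[0])
    beyond = np.nonzero(dev > track_length_cm / 2)[0]
    pivot = beyond[0] if beyond.size else int(np.argmax(dev))
    if s[pivot] < s[0]:
        s = track_length_cm - s
    return s


def compute_speed(position: PositionTrace, window_s: float = 0.3) -> SpeedTrace:
    """Instantaneous 2-D speed smoothed with a unit-sum Hamming window.

    Speed is the magnitude of the central-difference velocity (one-sided at
    the ends).  The Hamming kernel spans ``round(window_s * sample_rate)``
    samples and is renormalised at the trace edges so a constant speed is
    preserved everywhere.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t, x, y = position.t, position.x, position.y
    if t.size < 3:
        raise DataError("need at least 3 samples to compute speed")
    dt = np.diff(t)
    if dt.std() > 0.1 * dt.mean():
        warnings.warn("position sampling jitter exceeds 10%", stacklevel=2)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    v = np.hypot(vx, vy)
    n_win = max(1, round(window_s * position.sample_rate))
    if n_win > t.size:
        raise ValueError("smoothing window longer than the trace")
    if n_win > 1:
        kernel = np.hamming(n_win)
        kernel /= kernel.sum()
        num = np.convolve(v, kernel, mode="same")
        den = np.convolve(np.ones_like(v), kernel, mode="same")
        v = num / den
    return SpeedTrace(t=t, v=v)


def active_mask(s: np.ndarray, speed: SpeedTrace, cfg: AnalysisConfig,
                track_length_cm: float) -> np.ndarray:
    """Samples that enter the analysis: fast enough and outside reward zones.

    Strictly greater on speed, inclusive on the positional bounds.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != speed.v.shape:
        raise DataError("coordinate and speed traces are not aligned")
    m = cfg.reward_margin_cm
    return (speed.v > cfg.speed_threshold_cm_s) & (s >= m) & (s <= track_length_cm - m)


def segment_laps(t: np.ndarray, s: np.ndarray, track_length_cm: float,
                 reward_margin_cm: float = 9.0) -> tuple[list[LapSegment], int]:
    """Segment complete end-to-end traversals from reward-zone crossings.

    A lap runs from the moment the animal leaves one reward zone moving
    inward until it enters the opposite zone.  Excursions that return to the
    same zone (mid-track turn-arounds) are discarded; the second return value
    counts them.

    Raises
    ------
    DataError
        If no complete lap exists.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    lo = reward_margin_cm
    hi = track_length_cm - reward_margin_cm
    zone = np.zeros(s.size, dtype=int)
    zone[s < lo] = -1
    zone[s > hi] = 1
    # visits to end zones, in order: (sign, first sample index, last index)
    nz = np.nonzero(zone)[0]
    if nz.size == 0:
        raise DataError("trajectory never reaches a reward zone")
    breaks = np.nonzero(
        (np.diff(nz) > 1) | (zone[nz[1:]] != zone[nz[:-1]])
    )[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [nz.size - 1]])
    visits = [(int(zone[nz[a]]), int(nz[a]), int(nz[b])) for a, b in zip(starts, ends)]

    laps: list[LapSegment] = []
    n_discarded = 0
    for (sign_a, _, last_a), (sign_b, first_b, _) in zip(visits[:-1], visits[1:]):
        if sign_b == sign_a:
            n_discarded += 1  # returned to the same zone: not a traversal
            continue
        start_idx = last_a + 1  # first mid-track sample after leaving the zone
        laps.append(
            LapSegment(
                index=len(laps),
                t_start=float(t[min(start_idx, first_b)]),
                t_end=float(t[first_b]),
                direction=sign_b,
            )
        )
    if not laps:
        raise DataError("zero complete laps in trajectory")
    return laps, n_discarded


def sample_directions(t: np.ndarray, s: np.ndarray, laps: list[LapSegment]) -> np.ndarray:
    """Running direction (+1/-1, 0 = unassigned) for every position sample.

    Samples inside a lap inherit the lap direction.  Samples outside any lap
    (pauses, discarded turn-arounds) fall back to the sign of the local
    displacement, so mask-passing samples can still contribute to directional
    occupancy even when lap membership is undefined.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    d = np.sign(np.gradient(s, t)).astype(int)
    for lap in laps:
        inside = (t >= lap.t_start) & (t <= lap.t_end)
        d[inside] = lap.direction
    return d
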