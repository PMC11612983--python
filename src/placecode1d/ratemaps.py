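"""Directional occupancy and firing-rate profiles on the spatial grid.

Occupancy is the summed dwell time of mask-passing samples per bin and per
running direction; a rate profile divides per-bin spike counts (spikes
assigned to the interpolated position at their timestamp) by that occupancy.
Spatial information and place-field metrics operate on the raw profiles;
the 6-cm Gaussian smoothing and the peak/area normalisations used by the
population-vector and overlap analyses live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DataError, SpikeTrain
from .preprocess import BinGrid, bin_index

__all__ = [
    "NormalizationError",
    "Occupancy",
    "DirectionalRateProfile",
    "dwell_times",
    "occupancy",
    "rate_profile",
    "smooth_profile",
    "normalize_peak",
    "normalize_area",
]


class NormalizationError(ValueError):
    """Raised when a zero profile cannot be normalised."""


@dataclass
class Occupancy:
    """Seconds spent per spatial bin during active behaviour, one direction."""

    seconds: np.ndarray
    direction: int

    @property
    def total(self) -> float:
        return float(self.seconds.sum())

    @property
    def prob(self) -> np.ndarray:
        """Occupancy probability P_i (normalised dwell time)."""
        return self.seconds / self.total


@dataclass
class DirectionalRateProfile:
    """Binned firing rate of one unit in one running direction.

    ``rate`` is count/occupancy where occupancy is positive and 0 in
    unvisited bins (flagged in ``unvisited`` so downstream metrics can skip
    them rather than propagate NaN).
    """

    unit_id: str
    direction: int
    rate: np.ndarray
    count: np.ndarray
    occupancy: Occupancy

    @property
    def peak_rate(self) -> float:
        return float(self.rate.max())

    @property
    def unvisited(self) -> np.ndarray:
        return self.occupancy.seconds == 0


def dwell_times(t: np.ndarray) -> np.ndarray:
    """Per-sample dwell time: half the span between neighbouring samples."""
    t = np.asarray(t, dtype=float)
    w = np.empty_like(t)
    w[1:-1] = (t[2:] - t[:-2]) / 2
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    return w


def occupancy(t, s, mask, directions, direction: int, grid: BinGrid) -> Occupancy:
    """Summed dwell time per bin over mask-true samples of one direction."""
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    sel = np.asarray(mask, bool) & (np.asarray(directions) == direction)
    w = dwell_times(t)[sel]
    if w.size == 0 or w.sum() <= 0:
        raise DataError(f"zero occupancy for direction {direction:+d}")
    idx = bin_index(s[sel], grid)
    seconds = np.bincount(idx, weights=w, minlength=grid.n_bins)
    return Occupancy(seconds=seconds, direction=direction)


def rate_profile(spikes: SpikeTrain, t, s, mask, directions, direction: int,
                 occ: Occupancy, grid: BinGrid) -> DirectionalRateProfile:
    """Per-bin firing rate of one unit during active samples of one direction.

    Each spike is placed at the linearly interpolated track coordinate at its
    timestamp; spikes whose nearest position sample is masked out or runs the
    other way are discarded.  A unit with no passing spikes yields a valid
    all-zero profile.
    """
    if occ.direction != direction:
        raise DataError("occupancy direction does not match requested direction")
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    mask = np.asarray(mask, bool)
    directions = np.asarray(directions)
    counts = np.zeros(grid.n_bins, dtype=float)
    if spikes.n_spikes:
        times = spikes.times
        # nearest sample decides mask/direction membership
        right = np.clip(np.searchsorted(t, times), 1, t.size - 1)
        left = right - 1
        nearest = np.where(times - t[left] <= t[right] - times, left, right)
        keep = mask[nearest] & (directions[nearest] == direction)
        if keep.any():
            pos = np.interp(times[keep], t, s)
            np.add.at(counts, bin_index(pos, grid), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ.seconds > 0, counts / np.where(occ.seconds > 0, occ.seconds, 1.0), 0.0)
    return DirectionalRateProfile(
        unit_id=spikes.unit_id, direction=direction, rate=rate, count=counts, occupancy=occ
    )


def _as_rate(profile) -> np.ndarray:
    if isinstance(profile, DirectionalRateProfile):
        return profile.rate
    return np.asarray(profile, dtype=float)


def smooth_profile(profile, sigma_cm: float, grid: BinGrid) -> np.ndarray:
    """Gaussian smoothing (sigma in cm, truncated at 4 sigma, edge-corrected).

    The kernel is renormalised at the track ends so a constant profile is
    exactly invariant; a delta profile spreads into Gaussian densities at
    integer bin offsets.
    """
    if sigma_cm <= 0:
        raise ValueError("sigma_cm must be positive")
    rate = _as_rate(profile)
    sigma_bins = sigma_cm / grid.bin_cm
    half = int(np.ceil(4 * sigma_bins))
    offs = np.arange(-half, half + 1)
    kernel = np.exp(-(offs**2) / (2 * sigma_bins**2))
    kernel /= kernel.sum()
    num = np.convolve(rate, kernel, mode="same")
    den = np.convolve(np.ones_like(rate), kernel, mode="same")
    return num / den


def normalize_peak(profile) -> np.ndarray:
    """Scale a profile so its maximum equals 1."""
    rate = _as_rate(profile)
    peak = rate.max()
    if peak <= 0:
        raise NormalizationError("cannot peak-normalize an all-zero profile")
    return rate / peak


def normalize_area(profile) -> np.ndarray:
    """Area normalisation: scale so the profile sums to the number of bins.

    This is the normalisation entering the overlap index: a uniform profile
    maps to all ones, a delta to a single bin holding n_bins.
    """
    rate = _as_rate(profile)
    total = rate.sum()
    if total <= 0:
        raise NormalizationError("cannot area-normalize an all-zero profile")
    return rate.size * rate / total
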