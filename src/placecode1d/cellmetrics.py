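"""Single-cell place-coding statistics.

Implements the per-cell measures used to compare groups: Skaggs spatial
information (bits/spike), place-field size (width of the region above 20% of
the peak rate), the overlap index between the two running directions with
the resulting UC/NOBC/OBC/NCC classification, centre-of-mass distances, the
per-trial directionality index, per-lap rates and their normalisation, and
the mean-rate criterion selecting putative pyramidal cells.

Conventions
-----------
* Spatial information and place-field size are computed on *unsmoothed*
  profiles; smoothing enters only the population-vector analysis.
* A cell's session-level SI is the larger of its two directional values;
  its session-level PFs comes from the direction with the higher peak rate.
* Directionality-index trials pair consecutive opposite-direction laps in
  temporal order (odd trailing lap dropped).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import AnalysisConfig, DataError
from .preprocess import BinGrid, LapSegment
from .ratemaps import DirectionalRateProfile, Occupancy, normalize_area

__all__ = [
    "MetricUndefinedError",
    "CellClassification",
    "DITimecourse",
    "select_pyramidal",
    "spatial_information",
    "place_field_size",
    "overlap_index",
    "classify_cell",
    "center_of_mass",
    "com_distance",
    "directionality_index",
    "lap_mean_rates",
    "pair_trials",
    "di_timecourse",
    "normalized_firing_rate",
]

CLASS_UC = "UC"
CLASS_NOBC = "NOBC"
CLASS_OBC = "OBC"
CLASS_NCC = "NCC"


class MetricUndefinedError(ValueError):
    """A metric is undefined for this input (e.g. a silent cell)."""


@dataclass(frozen=True)
class CellClassification:
    """Directional class of one cell with the quantities that decided it."""

    unit_id: str
    label: str  # UC / NOBC / OBC / NCC
    oi: float  # NaN when undefined
    peak_right: float
    peak_left: float
    reason: str

    @property
    def merged_label(self) -> str:
        """Two-category scheme merging NOBC into UC (single prominent peak)."""
        return CLASS_UC if self.label == CLASS_NOBC else self.label


def _rates(profile) -> np.ndarray:
    if isinstance(profile, DirectionalRateProfile):
        return profile.rate
    return np.asarray(profile, dtype=float)


def select_pyramidal(mean_rates_hz: np.ndarray,
                     rate_range_hz: tuple[float, float] = (0.1, 6.0)) -> np.ndarray:
    """Boolean selector for units whose cross-session mean rate is pyramidal-like.

    The interval is closed on both ends; refractory-period and stability
    checks happen upstream during spike sorting.
    """
    r = np.asarray(mean_rates_hz, dtype=float)
    lo, hi = rate_range_hz
    return (r >= lo) & (r <= hi)


def spatial_information(profile, occ, n_spikes: int | None = None,
                        bias_correction: bool = False) -> float:
    """Skaggs spatial information in bits per spike.

        SI = sum_i P_i (R_i / R) log2(R_i / R)

    with P_i the occupancy probability of bin i, R_i the bin rate and
    R = sum_i P_i R_i the overall mean rate.  Bins with zero occupancy are
    excluded; bins with zero rate contribute nothing.  The optional
    first-order finite-sampling correction subtracts (m - 1)/(2 N ln 2)
    (m = occupied bins, N = spike count).

    Raises
    ------
    MetricUndefinedError
        For a silent cell (R = 0).
    """
    rate = _rates(profile)
    occ_s = occ.seconds if isinstance(occ, Occupancy) else np.asarray(occ, dtype=float)
    if rate.shape != occ_s.shape:
        raise DataError("profile and occupancy have different lengths")
    visited = occ_s > 0
    if not visited.any():
        raise DataError("occupancy is empty")
    p = occ_s[visited] / occ_s[visited].sum()
    r = rate[visited]
    mean_rate = float(np.dot(p, r))
    if mean_rate <= 0:
        raise MetricUndefinedError("silent cell: spatial information undefined")
    firing = r > 0
    ratio = r[firing] / mean_rate
    si = float(np.dot(p[firing] * ratio, np.log2(ratio)))
    if bias_correction:
        if n_spikes is None:
            if isinstance(profile, DirectionalRateProfile):
                n_spikes = int(profile.count.sum())
            else:
                raise ValueError("bias_correction requires n_spikes")
        if n_spikes > 0:
            si -= (int(visited.sum()) - 1) / (2 * n_spikes * math.log(2))
    return si


def place_field_size(profile, bin_cm: float = 3.0, interpolate: bool = False) -> float:
    """Place-field size: width of the region above 20% of the peak rate.

    The field is the maximal contiguous run of bins with rate >= 0.2 x peak
    that contains the global peak bin (the region under the upper 80% of the
    profile); its length in cm is the field size.  With ``interpolate`` the
    borders are refined by linear interpolation between bin centres instead
    of counting whole bins.
    """
    rate = _rates(profile)
    peak = rate.max()
    if peak <= 0:
        raise MetricUndefinedError("silent profile: place field size undefined")
    thr = 0.2 * peak
    above = rate >= thr
    p = int(np.argmax(rate))
    left = p
    while left > 0 and above[left - 1]:
        left -= 1
    right = p
    while right < rate.size - 1 and above[right + 1]:
        right += 1
    if not interpolate:
        return (right - left + 1) * bin_cm
    # refine each border by the sub-bin crossing of the 20% level
    width = (right - left) * bin_cm
    if left > 0:
        width += bin_cm * (rate[left] - thr) / (rate[left] - rate[left - 1])
    else:
        width += 0.5 * bin_cm
    if right < rate.size - 1:
        width += bin_cm * (rate[right] - thr) / (rate[right] - rate[right + 1])
    else:
        width += 0.5 * bin_cm
    return float(width)


def overlap_index(profile_right, profile_left) -> float:
    """Overlap index between the two directional profiles, in [0, 1].

    Both profiles are area-normalised to sum to the bin count; the index is

        r = 2 sum_phi min(Pr, Pl) / sum_phi (Pr + Pl)

    which equals sum(min)/n_bins.  It is 1 for identical profiles, 0 for
    disjoint supports, symmetric, and invariant to rescaling either profile.
    """
    pr = normalize_area(_rates(profile_right))
    pl = normalize_area(_rates(profile_left))
    if pr.shape != pl.shape:
        raise DataError("directional profiles have different lengths")
    return float(2 * np.minimum(pr, pl).sum() / (pr.sum() + pl.sum()))


def center_of_mass(profile, bin_cm: float = 3.0) -> float:
    """Rate-weighted mean position (cm), using bin centres (i + 0.5) * bin_cm."""
    rate = _rates(profile)
    total = rate.sum()
    if total <= 0:
        raise MetricUndefinedError("silent profile: centre of mass undefined")
    centers = (np.arange(rate.size) + 0.5) * bin_cm
    return float(np.dot(rate, centers) / total)


def com_distance(profile_right, profile_left, bin_cm: float = 3.0) -> float:
    """Absolute distance between the two directional centres of mass (cm)."""
    return abs(center_of_mass(profile_right, bin_cm) - center_of_mass(profile_left, bin_cm))


def classify_cell(profile_right, profile_left, cfg: AnalysisConfig,
                  grid: BinGrid, unit_id: str = "") -> CellClassification:
    """Directional classification of one cell.

    A direction is *valid* when its peak rate reaches ``cfg.peak_min_hz``
    (1.2 Hz) and the peak lies outside the reward margins.  Two valid
    directions make the cell bidirectional: OBC when the overlap index
    exceeds ``cfg.oi_threshold`` (0.4), NOBC otherwise.  Exactly one valid
    direction gives a unidirectional cell (UC).  Cells whose supra-threshold
    peaks all sit inside a reward zone, or with no supra-threshold peak at
    all, are non-classified (NCC).
    """
    rr, rl = _rates(profile_right), _rates(profile_left)
    if isinstance(profile_right, DirectionalRateProfile) and not unit_id:
        unit_id = profile_right.unit_id
    peaks = np.array([rr.max(), rl.max()])
    centers = grid.centers
    peak_pos = np.array([centers[int(np.argmax(rr))], centers[int(np.argmax(rl))]])
    supra = peaks >= cfg.peak_min_hz
    in_margin = (peak_pos < cfg.reward_margin_cm) | (
        peak_pos > grid.track_length_cm - cfg.reward_margin_cm
    )
    valid = supra & ~in_margin

    oi = math.nan
    if rr.sum() > 0 and rl.sum() > 0:
        oi = overlap_index(rr, rl)

    if valid.sum() == 2:
        if oi > cfg.oi_threshold:
            label, reason = CLASS_OBC, f"bidirectional, OI={oi:.3f} > {cfg.oi_threshold}"
        else:
            label, reason = CLASS_NOBC, f"bidirectional, OI={oi:.3f} <= {cfg.oi_threshold}"
    elif valid.sum() == 1:
        which = "rightward" if valid[0] else "leftward"
        label, reason = CLASS_UC, f"single supra-threshold peak ({which})"
    elif supra.any():
        label, reason = CLASS_NCC, "supra-threshold peak(s) inside reward margin"
    else:
        label, reason = CLASS_NCC, f"no peak >= {cfg.peak_min_hz} Hz"
    return CellClassification(
        unit_id=unit_id, label=label, oi=oi,
        peak_right=float(peaks[0]), peak_left=float(peaks[1]), reason=reason,
    )


# ---------------------------------------------------------------------------
# Per-lap rates and the directionality index
# ---------------------------------------------------------------------------

def directionality_index(rate_a: float, rate_b: float) -> float:
    """DI = |rA - rB| / (rA + rB): 0 = direction-blind, 1 = fully directional."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be non-negative")
    total = rate_a + rate_b
    if total <= 0:
        raise MetricUndefinedError("both rates zero: DI undefined")
    return abs(rate_a - rate_b) / total


def lap_mean_rates(spike_times: np.ndarray, laps: list[LapSegment]) -> np.ndarray:
    """Mean firing rate (Hz) of one unit inside each lap interval."""
    times = np.asarray(spike_times, dtype=float)
    out = np.empty(len(laps))
    for i, lap in enumerate(laps):
        n = np.searchsorted(times, lap.t_end, side="right") - np.searchsorted(
            times, lap.t_start, side="left"
        )
        out[i] = n / (lap.t_end - lap.t_start)
    return out


def pair_trials(laps: list[LapSegment]) -> list[tuple[int, int]]:
    """Pair consecutive opposite-direction laps into trials.

    Returns index pairs into ``laps``; a lap followed by another in the same
    direction is skipped, and an odd trailing lap is dropped.
    """
    pairs: list[tuple[int, int]] = []
    i = 0
    while i + 1 < len(laps):
        if laps[i].direction != laps[i + 1].direction:
            pairs.append((i, i + 1))
            i += 2
        else:
            i += 1
    return pairs


@dataclass
class DITimecourse:
    """Population directionality-index time course across trials.

    ``per_cell`` is (n_cells, n_trials) with NaN where a cell was silent in
    both directions of a trial; ``mean``/``sem``/``n`` summarise the
    population per trial.  ``first3``/``last3`` hold the per-cell averages
    over the first and last three trials (NaN when fewer than 3 trials).
    """

    per_cell: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    first3: np.ndarray
    last3: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.per_cell.shape[1]


def di_timecourse(cell_lap_rates: np.ndarray | list[np.ndarray],
                  laps: list[LapSegment]) -> DITimecourse:
    """Per-trial directionality index for a cell population.

    Parameters
    ----------
    cell_lap_rates : (n_cells, n_laps) array
        Mean rate of each cell in each lap (see :func:`lap_mean_rates`).
    laps : list of LapSegment
        The laps the columns refer to, in temporal order.
    """
    rates = np.atleast_2d(np.asarray(cell_lap_rates, dtype=float))
    if rates.shape[1] != len(laps):
        raise DataError("lap-rate matrix does not match the lap list")
    pairs = pair_trials(laps)
    if not pairs:
        raise DataError("no complete direction pair of laps")
    n_cells = rates.shape[0]
    per_cell = np.full((n_cells, len(pairs)), np.nan)
    for k, (i, j) in enumerate(pairs):
        a, b = rates[:, i], rates[:, j]
        total = a + b
        ok = total > 0
        per_cell[ok, k] = np.abs(a[ok] - b[ok]) / total[ok]
    n = np.sum(~np.isnan(per_cell), axis=0)
    with warnings.catch_warnings():
        # all-NaN trials and single-cell trials legitimately yield NaN summaries
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_cell, axis=0)
        sd = np.nanstd(per_cell, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        if len(pairs) >= 3:
            first3 = np.nanmean(per_cell[:, :3], axis=1)
            last3 = np.nanmean(per_cell[:, -3:], axis=1)
        else:
            first3 = np.full(n_cells, np.nan)
            last3 = np.full(n_cells, np.nan)
    return DITimecourse(per_cell=per_cell, mean=mean, sem=sem, n=n,
                        first3=first3, last3=last3)


def normalized_firing_rate(lap_rates_by_session: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Scale one cell's per-lap rates by its maximum across both sessions.

    The output maximum is exactly 1; a cell silent in every lap of every
    session has no defined normalisation.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in lap_rates_by_session.items()}
    peak = max((a.max() for a in arrays.values() if a.size), default=0.0)
    if peak <= 0:
        raise MetricUndefinedError("silent cell: normalized rate undefined")
    return {k: a / peak for k, a in arrays.items()}
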