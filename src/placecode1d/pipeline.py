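"""Session- and cohort-level orchestration.

``analyze_session`` runs the full single-session chain — track projection,
speed filtering, lap segmentation, directional occupancy and rate profiles —
and collects every per-cell metric into one tidy DataFrame.
``analyze_cohort`` applies it across sessions, adds the cross-session
pyramidal-rate selection, and returns one row per (session, unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellmetrics as cm
from . import population as pop
from . import preprocess as pre
from . import ratemaps as rm
from .core_io import AnalysisConfig, SessionRecord

__all__ = ["SessionAnalysis", "analyze_session", "analyze_cohort",
           "population_analysis", "di_analysis"]

DIR_RIGHT = 1
DIR_LEFT = -1


@dataclass
class SessionAnalysis:
    """Everything derived from one session."""

    session: SessionRecord
    cfg: AnalysisConfig
    grid: pre.BinGrid
    s: np.ndarray
    speed: pre.SpeedTrace
    mask: np.ndarray
    laps: list[pre.LapSegment]
    n_discarded_excursions: int
    directions: np.ndarray
    occupancy: dict[int, rm.Occupancy]
    profiles: dict[str, dict[int, rm.DirectionalRateProfile]]
    lap_rates: dict[str, np.ndarray]
    metrics: pd.DataFrame = field(repr=False, default=None)


def analyze_session(session: SessionRecord, cfg: AnalysisConfig | None = None) -> SessionAnalysis:
    """Run the single-session pipeline and compute all per-cell metrics.

    The metrics frame has one row per unit with directional and collapsed
    spatial information, place-field sizes, peak rates, overlap index,
    classification, centre-of-mass distance and overall mean rate.  Metrics
    undefined for a unit (silent direction, sub-threshold peaks) are NaN.
    """
    cfg = cfg or AnalysisConfig()
    grid = pre.make_grid(session.track_length_cm, cfg.bin_cm)
    s = pre.project_to_track(session.position, session.track_length_cm)
    speed = pre.compute_speed(session.position, cfg.hamming_window_s)
    mask = pre.active_mask(s, speed, cfg, session.track_length_cm)
    laps, n_discarded = pre.segment_laps(
        session.position.t, s, session.track_length_cm, cfg.reward_margin_cm
    )
    directions = pre.sample_directions(session.position.t, s, laps)
    t = session.position.t
    occ = {
        d: rm.occupancy(t, s, mask, directions, d, grid)
        for d in (DIR_RIGHT, DIR_LEFT)
    }

    profiles: dict[str, dict[int, rm.DirectionalRateProfile]] = {}
    lap_rates: dict[str, np.ndarray] = {}
    rows = []
    duration = session.duration
    for unit in session.units:
        per_dir = {
            d: rm.rate_profile(unit, t, s, mask, directions, d, occ[d], grid)
            for d in (DIR_RIGHT, DIR_LEFT)
        }
        profiles[unit.unit_id] = per_dir
        lap_rates[unit.unit_id] = cm.lap_mean_rates(unit.times, laps)
        row = _unit_metrics(unit.unit_id, per_dir, occ, cfg, grid)
        row["mean_rate_hz"] = unit.n_spikes / duration
        row["n_spikes"] = unit.n_spikes
        rows.append(row)

    metrics = pd.DataFrame(rows)
    if not metrics.empty:
        metrics.insert(0, "animal_id", session.animal_id)
        metrics.insert(1, "group", session.group)
        metrics.insert(2, "environment", session.environment)
    return SessionAnalysis(
        session=session, cfg=cfg, grid=grid, s=s, speed=speed, mask=mask,
        laps=laps, n_discarded_excursions=n_discarded, directions=directions,
        occupancy=occ, profiles=profiles, lap_rates=lap_rates, metrics=metrics,
    )


def _unit_metrics(unit_id, per_dir, occ, cfg, grid) -> dict:
    out: dict = {"unit_id": unit_id}
    si = {}
    pfs = {}
    for d, name in ((DIR_RIGHT, "right"), (DIR_LEFT, "left")):
        prof = per_dir[d]
        out[f"peak_{name}_hz"] = prof.peak_rate
        try:
            si[name] = cm.spatial_information(prof, occ[d])
        except cm.MetricUndefinedError:
            si[name] = np.nan
        try:
            pfs[name] = cm.place_field_size(prof, grid.bin_cm)
        except cm.MetricUndefinedError:
            pfs[name] = np.nan
        out[f"si_{name}"] = si[name]
        out[f"pfs_{name}_cm"] = pfs[name]
    out["si"] = np.nanmax([si["right"], si["left"]]) if not all(
        np.isnan(v) for v in si.values()
    ) else np.nan
    # collapsed PFs follows the dominant (higher-peak) direction
    dominant = "right" if out["peak_right_hz"] >= out["peak_left_hz"] else "left"
    out["pfs_cm"] = pfs[dominant]
    cls = cm.classify_cell(per_dir[DIR_RIGHT], per_dir[DIR_LEFT], cfg, grid, unit_id)
    out["oi"] = cls.oi
    out["class"] = cls.label
    out["class_merged"] = cls.merged_label
    try:
        out["com_distance_cm"] = cm.com_distance(
            per_dir[DIR_RIGHT], per_dir[DIR_LEFT], grid.bin_cm
        )
    except cm.MetricUndefinedError:
        out["com_distance_cm"] = np.nan
    return out


def analyze_cohort(sessions: list[SessionRecord], cfg: AnalysisConfig | None = None,
                   pyramidal_only: bool = True,
                   ) -> tuple[pd.DataFrame, dict[tuple[str, str], SessionAnalysis]]:
    """Analyze a cohort of sessions into one tidy per-cell metrics frame.

    When both environments of an animal are present, units are kept only if
    their mean rate pooled across the two sessions falls in the pyramidal
    band (the criterion is applied per unit across both sessions, mirroring
    how units recorded through an experiment day are screened).
    """
    cfg = cfg or AnalysisConfig()
    analyses: dict[tuple[str, str], SessionAnalysis] = {}
    frames = []
    for sess in sessions:
        ana = analyze_session(sess, cfg)
        analyses[(sess.animal_id, sess.environment)] = ana
        frames.append(ana.metrics)
    metrics = pd.concat(frames, ignore_index=True)

    if pyramidal_only and not metrics.empty:
        pooled = (
            metrics.assign(
                dur=lambda df: [
                    analyses[(a, e)].session.duration
                    for a, e in zip(df.animal_id, df.environment)
                ]
            )
            .groupby(["animal_id", "unit_id"])
            .agg(total_spikes=("n_spikes", "sum"), total_dur=("dur", "sum"))
        )
        pooled["pooled_rate"] = pooled.total_spikes / pooled.total_dur
        keep = cm.select_pyramidal(
            pooled["pooled_rate"].to_numpy(), cfg.pyramidal_rate_range_hz
        )
        kept_idx = set(pooled.index[keep])
        metrics = metrics[
            [
                (a, u) in kept_idx
                for a, u in zip(metrics.animal_id, metrics.unit_id)
            ]
        ].reset_index(drop=True)
    return metrics, analyses


def population_analysis(ana: SessionAnalysis) -> dict:
    """Cross-direction population-vector correlation for one session.

    Returns the two population matrices, their cross-direction Pearson
    matrix and the offset-band peak score.
    """
    unit_ids = list(ana.profiles)
    mats = {}
    for d in (DIR_RIGHT, DIR_LEFT):
        mats[d], _ = pop.population_matrix(
            [ana.profiles[u][d] for u in unit_ids], ana.grid,
            ana.cfg.pv_smooth_sigma_cm,
        )
    corr = pop.pv_correlation(mats[DIR_RIGHT], mats[DIR_LEFT])
    score = pop.cross_direction_score(corr)
    return {
        "unit_ids": unit_ids,
        "matrix_right": mats[DIR_RIGHT],
        "matrix_left": mats[DIR_LEFT],
        "correlation": corr,
        "score": score.score,
        "offset": score.offset,
    }


def di_analysis(ana: SessionAnalysis) -> cm.DITimecourse:
    """Population directionality-index time course for one session."""
    unit_ids = list(ana.lap_rates)
    rates = np.vstack([ana.lap_rates[u] for u in unit_ids])
    return cm.di_timecourse(rates, ana.laps)
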