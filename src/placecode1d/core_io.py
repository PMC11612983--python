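"""Domain types, analysis configuration and session I/O.

A recording session couples one position trace (timestamps plus 2-D
coordinates in cm) with a set of sorted spike trains and the metadata needed
downstream (animal id, group, environment, track length).  The native on-disk
representation is a directory bundle of plain CSV tables plus a YAML metadata
file; an equivalent single-file HDF5 container is also supported.  Both
round-trip losslessly (floats are written at full precision).

All timestamps are session-relative seconds; all coordinates are centimetres.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataError",
    "ConfigError",
    "PositionTrace",
    "SpikeTrain",
    "SessionRecord",
    "AnalysisConfig",
    "read_session",
    "write_session",
]

GROUPS = ("control", "transgenic")
ENVIRONMENTS = ("familiar", "novel")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly through text


class DataError(ValueError):
    """Malformed or inconsistent recording data."""


class ConfigError(ValueError):
    """Missing or invalid configuration / metadata."""


@dataclass
class PositionTrace:
    """Timestamped 2-D tracking data.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Coordinates in cm.
    sample_rate : float
        Nominal tracking rate in Hz (recorded, not enforced; typical
        camera systems run near 50 Hz).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise DataError("t, x, y must have identical shapes")
        if self.t.ndim != 1 or self.t.size < 2:
            raise DataError("position trace needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(
            np.isfinite(self.x)
        ) or not np.all(np.isfinite(self.y)):
            raise DataError("position trace contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one putative pyramidal unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.unit_id = str(self.unit_id)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise DataError(f"unit {self.unit_id}: spike times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise DataError(f"unit {self.unit_id}: spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class SessionRecord:
    """One ~30-min linear-track session: position, units and labels."""

    animal_id: str
    group: str
    environment: str
    position: PositionTrace
    units: list[SpikeTrain] = field(default_factory=list)
    track_length_cm: float = 170.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.environment not in ENVIRONMENTS:
            raise ConfigError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        if self.track_length_cm <= 0:
            raise ConfigError("track_length_cm must be positive")

    def validate_spikes(self, reward_margin_cm: float = 9.0) -> int:
        """Drop spikes outside the recorded interval; return how many were cut.

        The track must also be long enough to hold two reward margins.
        """
        if self.track_length_cm <= 2 * reward_margin_cm:
            raise ConfigError("track shorter than twice the reward margin")
        t0, t1 = float(self.position.t[0]), float(self.position.t[-1])
        n_dropped = 0
        for i, u in enumerate(self.units):
            keep = (u.times >= t0) & (u.times <= t1)
            n_dropped += int((~keep).sum())
            if not keep.all():
                self.units[i] = SpikeTrain(u.unit_id, u.times[keep])
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} spike(s) outside the recording interval",
                stacklevel=2,
            )
        return n_dropped

    @property
    def duration(self) -> float:
        return self.position.duration


@dataclass
class AnalysisConfig:
    """All analysis parameters, with the defaults used throughout.

    bin_cm : spatial bin width (3 cm -> 57 bins on a 170 cm track).
    speed_threshold_cm_s : samples at or below this speed are excluded.
    hamming_window_s : length of the Hamming kernel smoothing speed.
    reward_margin_cm : zone at each track end excluded from analysis.
    peak_min_hz : minimum in-field peak rate for a direction to count
        in the directional classification.
    oi_threshold : overlap-index cut separating overlapping from
        non-overlapping bidirectional cells.
    pv_smooth_sigma_cm : Gaussian sigma applied to profiles only for the
        population-vector analysis.
    pyramidal_rate_range_hz : closed mean-rate interval selecting putative
        pyramidal cells across both sessions.
    n_bootstrap : resamples per bootstrap comparison.
    """

    bin_cm: float = 3.0
    speed_threshold_cm_s: float = 3.0
    hamming_window_s: float = 0.3
    reward_margin_cm: float = 9.0
    peak_min_hz: float = 1.2
    oi_threshold: float = 0.4
    pv_smooth_sigma_cm: float = 6.0
    pyramidal_rate_range_hz: tuple[float, float] = (0.1, 6.0)
    n_bootstrap: int = 10000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bin_cm",
            "speed_threshold_cm_s",
            "hamming_window_s",
            "reward_margin_cm",
            "peak_min_hz",
            "pv_smooth_sigma_cm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0.0 < self.oi_threshold < 1.0):
            raise ConfigError("oi_threshold must lie in (0, 1)")
        lo, hi = self.pyramidal_rate_range_hz
        if not (0 < lo < hi):
            raise ConfigError("pyramidal_rate_range_hz must be increasing and positive")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["pyramidal_rate_range_hz"] = list(self.pyramidal_rate_range_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "pyramidal_rate_range_hz" in raw:
            raw["pyramidal_rate_range_hz"] = tuple(raw["pyramidal_rate_range_hz"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("animal_id", "group", "environment", "track_length_cm", "sample_rate")


def write_session(session: SessionRecord, path: str | Path, format: str = "csv-bundle") -> None:
    """Write a session to disk.

    ``csv-bundle`` writes a directory with ``position.csv`` (t,x,y),
    ``spikes.csv`` (unit_id,t) and ``meta.yaml``; ``hdf5`` writes a single
    file.  Either representation round-trips bit-exact through
    :func:`read_session`.
    """
    path = Path(path)
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        pos = session.position
        pd.DataFrame({"t": pos.t, "x": pos.x, "y": pos.y}).to_csv(
            path / "position.csv", index=False, float_format=_FLOAT_FMT
        )
        if session.units:
            spikes = pd.concat(
                [
                    pd.DataFrame({"unit_id": u.unit_id, "t": u.times})
                    for u in session.units
                ],
                ignore_index=True,
            )
        else:
            spikes = pd.DataFrame({"unit_id": pd.Series(dtype=str), "t": pd.Series(dtype=float)})
        spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)
        # unit order must survive the round trip even for silent units
        meta = {
            "animal_id": session.animal_id,
            "group": session.group,
            "environment": session.environment,
            "track_length_cm": float(session.track_length_cm),
            "sample_rate": float(pos.sample_rate),
            "unit_ids": [u.unit_id for u in session.units],
        }
        (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group("position")
            g.create_dataset("t", data=session.position.t)
            g.create_dataset("x", data=session.position.x)
            g.create_dataset("y", data=session.position.y)
            f.attrs["animal_id"] = session.animal_id
            f.attrs["group"] = session.group
            f.attrs["environment"] = session.environment
            f.attrs["track_length_cm"] = float(session.track_length_cm)
            f.attrs["sample_rate"] = float(session.position.sample_rate)
            units = f.create_group("units")
            f.attrs["unit_order"] = [u.unit_id for u in session.units]
            for u in session.units:
                units.create_dataset(u.unit_id, data=u.times)
    else:
        raise ConfigError(f"unknown session format {format!r}")


def read_session(path: str | Path, format: str = "csv-bundle") -> SessionRecord:
    """Read a session written by :func:`write_session` and validate it.

    Spike times outside the recorded interval are dropped with a warning.
    """
    path = Path(path)
    if format == "csv-bundle":
        if not path.is_dir():
            raise DataError(f"session bundle {path} is not a directory")
        pos_file = path / "position.csv"
        meta_file = path / "meta.yaml"
        spikes_file = path / "spikes.csv"
        if not pos_file.exists():
            raise DataError(f"bundle {path} is missing position.csv")
        if not spikes_file.exists():
            raise DataError(f"bundle {path} is missing spikes.csv")
        if not meta_file.exists():
            raise ConfigError(f"bundle {path} is missing meta.yaml")
        meta = yaml.safe_load(meta_file.read_text())
        for key in _META_KEYS:
            if key not in meta:
                raise ConfigError(f"meta.yaml is missing key {key!r}")
        pos_df = pd.read_csv(pos_file, float_precision="round_trip")
        spikes_df = pd.read_csv(
            spikes_file, dtype={"unit_id": str}, float_precision="round_trip"
        )
        position = PositionTrace(
            pos_df["t"].to_numpy(),
            pos_df["x"].to_numpy(),
            pos_df["y"].to_numpy(),
            sample_rate=float(meta["sample_rate"]),
        )
        by_unit = {
            uid: g["t"].to_numpy() for uid, g in spikes_df.groupby("unit_id", sort=False)
        }
        order = meta.get("unit_ids", list(by_unit))
        units = [SpikeTrain(uid, by_unit.get(uid, np.empty(0))) for uid in order]
        session = SessionRecord(
            animal_id=str(meta["animal_id"]),
            group=str(meta["group"]),
            environment=str(meta["environment"]),
            position=position,
            units=units,
            track_length_cm=float(meta["track_length_cm"]),
        )
    elif format == "hdf5":
        if not path.exists():
            raise DataError(f"session file {path} does not exist")
        with h5py.File(path, "r") as f:
            for key in ("animal_id", "group", "environment", "track_length_cm", "sample_rate"):
                if key not in f.attrs:
                    raise ConfigError(f"HDF5 session is missing attribute {key!r}")
            position = PositionTrace(
                f["position/t"][...],
                f["position/x"][...],
                f["position/y"][...],
                sample_rate=float(f.attrs["sample_rate"]),
            )
            order = [str(u) for u in f.attrs.get("unit_order", list(f["units"]))]
            units = [SpikeTrain(uid, f["units"][uid][...]) for uid in order]
            session = SessionRecord(
                animal_id=str(f.attrs["animal_id"]),
                group=str(f.attrs["group"]),
                environment=str(f.attrs["environment"]),
                position=position,
                units=units,
                track_length_cm=float(f.attrs["track_length_cm"]),
            )
    else:
        raise ConfigError(f"unknown session format {format!r}")
    session.validate_spikes()
    return session
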