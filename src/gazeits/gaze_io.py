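"""Data model and I/O for binocular gaze recordings.

A recording is a uniformly sampled table of left/right gaze positions,
left/right pupil diameters and a per-sample validity flag.  Gaze positions are
carried in degrees of visual angle by default; a pixel dialect must declare a
pixels-per-degree factor so dispersion thresholds keep their degree semantics.

The interchange format is plain CSV with one row per sample and columns::

    trial_id, participant_id, task_id, condition, t, lx, ly, rx, ry, lp, rp, valid

Trials are grouped by ``trial_id``; any non-finite gaze cell marks the sample
invalid on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GazeRecording",
    "Trial",
    "DatasetConfig",
    "FormatError",
    "DataError",
    "read_trials",
    "write_trials",
    "trim_trial",
]

CSV_COLUMNS = [
    "trial_id",
    "participant_id",
    "task_id",
    "condition",
    "t",
    "lx",
    "ly",
    "rx",
    "ry",
    "lp",
    "rp",
    "valid",
]


class FormatError(ValueError):
    """Malformed input table (missing column, bad dialect)."""


class DataError(ValueError):
    """Well-formed table with inconsistent content (e.g. non-monotone time)."""


@dataclass
class GazeRecording:
    """One trial's uniformly sampled binocular gaze/pupil channels.

    All channel arrays share one length; ``timestamps`` are seconds from trial
    start and must be strictly increasing, consistent with ``sampling_rate``
    within one sample period.
    """

    sampling_rate: float
    timestamps: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    left_pupil: np.ndarray
    right_pupil: np.ndarray
    valid: np.ndarray
    units: str = "deg"

    def __post_init__(self) -> None:
        arrays = [
            self.timestamps,
            self.left_x,
            self.left_y,
            self.right_x,
            self.right_y,
            self.left_pupil,
            self.right_pupil,
            self.valid,
        ]
        for name in ("timestamps", "left_x", "left_y", "right_x", "right_y",
                     "left_pupil", "right_pupil"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if n < 1:
            raise DataError("recording must contain at least one sample")
        if any(len(a) != n for a in arrays):
            raise DataError("channel lengths differ")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        dt = np.diff(self.timestamps)
        if n > 1 and np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        period = 1.0 / self.sampling_rate
        if n > 1 and np.any(np.abs(dt - period) > period):
            raise DataError("timestamps inconsistent with sampling_rate")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (sample count over rate)."""
        return self.n_samples / self.sampling_rate

    def mean_gaze(self) -> tuple[np.ndarray, np.ndarray]:
        """Two-eye average gaze stream (x, y)."""
        return (
            0.5 * (self.left_x + self.right_x),
            0.5 * (self.left_y + self.right_y),
        )


@dataclass
class Trial:
    """A recording plus its labels: participant, task, binary condition."""

    recording: GazeRecording
    trial_id: str
    participant_id: str
    task_id: str
    condition: str
    dataset_id: str = ""


@dataclass
class DatasetConfig:
    """Dialect and standardization settings for one dataset.

    ``pixels_per_degree`` converts a pixel-unit source to the canonical
    degrees; leave ``None`` for degree-native sources.
    """

    sampling_rate_hz: float
    trial_length_s: float
    units: str = "deg"
    column_map: dict[str, str] = field(default_factory=dict)
    pixels_per_degree: float | None = None

    def __post_init__(self) -> None:
        if self.trial_length_s <= 0:
            raise FormatError("trial_length_s must be positive")
        if self.units not in ("deg", "px"):
            raise FormatError(f"unknown units {self.units!r}")
        if self.units == "px" and not self.pixels_per_degree:
            raise FormatError("pixel units require pixels_per_degree")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "sampling_rate_hz": self.sampling_rate_hz,
                    "trial_length_s": self.trial_length_s,
                    "units": self.units,
                    "column_map": dict(self.column_map),
                    "pixels_per_degree": self.pixels_per_degree,
                },
                fh,
            )


def _resolve_columns(df: pd.DataFrame, config: DatasetConfig) -> pd.DataFrame:
    if config.column_map:
        df = df.rename(columns={v: k for k, v in config.column_map.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    return df


def read_trials(path: str | Path, config: DatasetConfig) -> list[Trial]:
    """Read trials from a delimited-text table, grouped by ``trial_id``.

    Samples whose gaze cells are empty or non-finite get ``valid=False``.
    Pixel-unit sources are converted to degrees via ``pixels_per_degree``.
    """
    df = pd.read_csv(path, dtype={"trial_id": str, "participant_id": str,
                                  "task_id": str, "condition": str},
                     float_precision="round_trip")
    df = _resolve_columns(df, config)
    gaze_cols = ["lx", "ly", "rx", "ry"]
    scale = 1.0
    if config.units == "px":
        scale = 1.0 / float(config.pixels_per_degree)  # type: ignore[arg-type]
    trials: list[Trial] = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"non-monotone timestamps in trial {trial_id}")
        gaze = grp[gaze_cols].to_numpy(dtype=float) * scale
        valid = grp["valid"].to_numpy(dtype=bool) & np.isfinite(gaze).all(axis=1)
        rec = GazeRecording(
            sampling_rate=config.sampling_rate_hz,
            timestamps=t,
            left_x=gaze[:, 0],
            left_y=gaze[:, 1],
            right_x=gaze[:, 2],
            right_y=gaze[:, 3],
            left_pupil=grp["lp"].to_numpy(dtype=float),
            right_pupil=grp["rp"].to_numpy(dtype=float),
            valid=valid,
            units="deg",
        )
        trials.append(
            Trial(
                recording=rec,
                trial_id=str(trial_id),
                participant_id=str(grp["participant_id"].iloc[0]),
                task_id=str(grp["task_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return trials


def write_trials(trials: Sequence[Trial], path: str | Path,
                 config: DatasetConfig | None = None) -> None:
    """Write trials to CSV so that ``read_trials`` round-trips exactly.

    Channels are written in the canonical degrees with full float precision.
    """
    if not trials:
        raise DataError("empty trial collection")
    frames = []
    for tr in trials:
        rec = tr.recording
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "participant_id": tr.participant_id,
                    "task_id": tr.task_id,
                    "condition": tr.condition,
                    "t": rec.timestamps,
                    "lx": rec.left_x,
                    "ly": rec.left_y,
                    "rx": rec.right_x,
                    "ry": rec.right_y,
                    "lp": rec.left_pupil,
                    "rp": rec.right_pupil,
                    "valid": rec.valid,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def trim_trial(trial: Trial, target_length: float) -> Trial:
    """Cut a trial to its first ``target_length`` seconds.

    All trials of one dataset are standardized to one length by keeping the
    prefix: exactly ``floor(target_length * sampling_rate)`` samples.  Trials
    shorter than the target raise; padding is never applied.
    """
    rec = trial.recording
    n_target = int(np.floor(target_length * rec.sampling_rate))
    if rec.n_samples < n_target:
        raise DataError(
            f"trial {trial.trial_id}: {rec.n_samples} samples, "
            f"need {n_target} for {target_length} s at {rec.sampling_rate} Hz"
        )
    if rec.n_samples == n_target:
        return trial
    sl = slice(0, n_target)
    new_rec = GazeRecording(
        sampling_rate=rec.sampling_rate,
        timestamps=rec.timestamps[sl],
        left_x=rec.left_x[sl],
        left_y=rec.left_y[sl],
        right_x=rec.right_x[sl],
        right_y=rec.right_y[sl],
        left_pupil=rec.left_pupil[sl],
        right_pupil=rec.right_pupil[sl],
        valid=rec.valid[sl],
        units=rec.units,
    )
    return replace(trial, recording=new_rec)
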