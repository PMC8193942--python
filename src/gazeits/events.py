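"""Oculomotor event detection: blinks, I-DT fixations, saccades.

Blinks are maximal runs of invalid samples whose duration reaches the blink
threshold (50 ms by default); shorter invalid runs are treated as tracker
dropouts and linearly interpolated.  Fixations are found with the
dispersion-threshold identification algorithm (I-DT, Salvucci & Goldberg): a
window of at least the minimum fixation duration is grown while the Manhattan
dispersion (max x - min x) + (max y - min y) stays within the threshold
(1 degree by default).  Saccades are the gaps between consecutive fixations
that are not occupied by a blink; their amplitude is the Euclidean distance
between endpoint positions and peak velocity comes from a central-difference
velocity estimate.

Detection runs on the two-eye average gaze stream with blink samples removed
(the per-eye channels are kept for vergence features downstream).  Removing
blink samples rather than splitting at them mirrors the blink-filtering step
of the imaging pipeline and lets a fixation's samples be evaluated on the
positions that were actually tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .gaze_io import Trial

__all__ = [
    "EventConfig",
    "Blink",
    "Fixation",
    "Saccade",
    "OculomotorEvents",
    "detect_blinks",
    "detect_fixations_idt",
    "derive_saccades",
    "detect_events",
    "interpolate_short_gaps",
]


class UnitError(ValueError):
    pass


@dataclass
class EventConfig:
    blink_min_duration_ms: float = 50.0
    dispersion_threshold_deg: float = 1.0
    fixation_min_duration_ms: float = 100.0
    interpolate_gaps_below_ms: float = 50.0
    # post-step: re-join a fixation split by the greedy window (close in
    # time, same place); genuine neighbours are saccade-separated in space,
    # so the distance criterion is the discriminator.  The gap bound allows
    # for anchor windows skipped after a dispersion break (up to one
    # minimum-fixation window).
    merge_max_gap_ms: float = 100.0
    merge_max_distance_deg: float = 0.5

    def __post_init__(self) -> None:
        for name in ("blink_min_duration_ms", "dispersion_threshold_deg",
                     "fixation_min_duration_ms", "interpolate_gaps_below_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "EventConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class Blink:
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    centroid_x: float
    centroid_y: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Saccade:
    onset: float
    offset: float
    start_x: float
    start_y: float
    end_x: float
    end_y: float
    amplitude: float
    peak_velocity: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class OculomotorEvents:
    blinks: list[Blink] = field(default_factory=list)
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges [i, j) of maximal invalid runs."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_blinks(trial: Trial, config: EventConfig | None = None) -> list[Blink]:
    """Maximal invalid runs lasting at least the blink threshold."""
    config = config or EventConfig()
    rec = trial.recording
    fs = rec.sampling_rate
    min_samples = max(1, int(np.ceil(config.blink_min_duration_ms / 1000 * fs)))
    blinks = []
    for i, j in _invalid_runs(rec.valid):
        if j - i >= min_samples:
            # offset = end of last invalid sample's period
            blinks.append(Blink(rec.timestamps[i], rec.timestamps[j - 1] + 1 / fs))
    return blinks


def interpolate_short_gaps(x: np.ndarray, valid: np.ndarray,
                           max_gap_samples: int) -> np.ndarray:
    """Linearly interpolate invalid runs of at most ``max_gap_samples``."""
    x = x.astype(float).copy()
    n = len(x)
    for i, j in _invalid_runs(valid):
        if j - i > max_gap_samples:
            continue
        lo = i - 1
        hi = j
        if lo < 0 and hi >= n:
            continue
        if lo < 0:
            x[i:j] = x[hi]
        elif hi >= n:
            x[i:j] = x[lo]
        else:
            x[i:j] = np.interp(np.arange(i, j), [lo, hi], [x[lo], x[hi]])
    return x


def _prepared_streams(trial: Trial, config: EventConfig
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Average-eye gaze with short gaps interpolated and blink samples removed.

    Returns (t, x, y, keep_index) where ``keep_index`` maps back to the
    original sample grid.
    """
    rec = trial.recording
    fs = rec.sampling_rate
    gx, gy = rec.mean_gaze()
    max_gap = int(np.floor(config.interpolate_gaps_below_ms / 1000 * fs))
    blink_min = max(1, int(np.ceil(config.blink_min_duration_ms / 1000 * fs)))
    keep = np.ones(rec.n_samples, dtype=bool)
    for i, j in _invalid_runs(rec.valid):
        if j - i >= blink_min:
            keep[i:j] = False
    gx = interpolate_short_gaps(gx, rec.valid | ~keep, max_gap)
    gy = interpolate_short_gaps(gy, rec.valid | ~keep, max_gap)
    idx = np.flatnonzero(keep)
    return rec.timestamps[idx], gx[idx], gy[idx], idx


def detect_fixations_idt(trial: Trial, config: EventConfig | None = None
                         ) -> list[Fixation]:
    """Dispersion-threshold identification on the average gaze stream.

    Requires degree units (the 1-degree default threshold has degree
    semantics).  Blink samples are removed before the sweep; fixation onsets
    and offsets are reported on the original time axis.
    """
    config = config or EventConfig()
    rec = trial.recording
    if rec.units != "deg":
        raise UnitError("I-DT requires gaze in degrees; convert on read "
                        "(DatasetConfig.pixels_per_degree)")
    fs = rec.sampling_rate
    t, x, y, idx = _prepared_streams(trial, config)
    win = max(2, int(np.round(config.fixation_min_duration_ms / 1000 * fs)))
    thresh = config.dispersion_threshold_deg

    fixations: list[Fixation] = []
    # sweep each contiguous stretch separately so no fixation spans a blink
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1 if len(idx) else np.empty(0, int)
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(idx)]):
        fixations.extend(
            _idt_sweep(t[lo:hi], x[lo:hi], y[lo:hi], win, thresh, fs))
    return fixations


def _idt_sweep(t: np.ndarray, x: np.ndarray, y: np.ndarray,
               win: int, thresh: float, fs: float) -> list[Fixation]:
    n = len(x)
    fixations: list[Fixation] = []
    i = 0
    while i + win <= n:
        j = i + win
        d = (x[i:j].max() - x[i:j].min()) + (y[i:j].max() - y[i:j].min())
        if d <= thresh:
            xmin, xmax = x[i:j].min(), x[i:j].max()
            ymin, ymax = y[i:j].min(), y[i:j].max()
            while j < n:
                nxmin = min(xmin, x[j]); nxmax = max(xmax, x[j])
                nymin = min(ymin, y[j]); nymax = max(ymax, y[j])
                if (nxmax - nxmin) + (nymax - nymin) > thresh:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            fixations.append(Fixation(
                onset=float(t[i]),
                offset=float(t[j - 1] + 1 / fs),
                centroid_x=float(x[i:j].mean()),
                centroid_y=float(y[i:j].mean()),
            ))
            i = j
        else:
            i += 1
    return fixations


def derive_saccades(fixations: Sequence[Fixation], trial: Trial,
                    blinks: Sequence[Blink] = (),
                    config: EventConfig | None = None) -> list[Saccade]:
    """One saccade per inter-fixation gap not occupied by a blink.

    A gap counts as blink-occupied when a blink covers at least half of it;
    those gaps produce no saccade (the eyes were closed, not in flight).
    """
    config = config or EventConfig()
    rec = trial.recording
    fs = rec.sampling_rate
    gx, gy = rec.mean_gaze()
    max_gap = int(np.floor(config.interpolate_gaps_below_ms / 1000 * fs))
    gx = interpolate_short_gaps(gx, rec.valid, max_gap)
    gy = interpolate_short_gaps(gy, rec.valid, max_gap)
    # central-difference velocity, degrees/s
    if rec.n_samples >= 3:
        vx = np.gradient(gx, 1 / fs)
        vy = np.gradient(gy, 1 / fs)
        speed = np.hypot(vx, vy)
    else:
        speed = np.zeros(rec.n_samples)

    saccades: list[Saccade] = []
    for prev, nxt in zip(fixations, fixations[1:]):
        gap_on, gap_off = prev.offset, nxt.onset
        if gap_off <= gap_on:
            continue
        blink_cover = sum(
            max(0.0, min(b.offset, gap_off) - max(b.onset, gap_on))
            for b in blinks)
        if blink_cover >= 0.5 * (gap_off - gap_on):
            continue
        i0 = int(np.searchsorted(rec.timestamps, gap_on))
        i1 = int(np.searchsorted(rec.timestamps, gap_off))
        i1 = max(i1, i0 + 1)
        sx, sy = prev.centroid_x, prev.centroid_y
        ex, ey = nxt.centroid_x, nxt.centroid_y
        pv = float(speed[i0:i1].max()) if i1 > i0 else 0.0
        saccades.append(Saccade(
            onset=gap_on, offset=gap_off,
            start_x=sx, start_y=sy, end_x=ex, end_y=ey,
            amplitude=float(np.hypot(ex - sx, ey - sy)),
            peak_velocity=pv,
        ))
    return saccades


def merge_adjacent_fixations(fixations: Sequence[Fixation],
                             config: EventConfig | None = None
                             ) -> list[Fixation]:
    """Re-join fixations the greedy I-DT window split apart.

    The sweep can anchor its first window on the trailing samples of a
    saccade ramp, spend the dispersion budget on them, and cut the true
    fixation in two.  The pieces are adjacent in time and essentially in
    the same place, whereas genuinely distinct fixations are separated by
    a saccade (tens of ms *and* degrees apart) — so merging pairs closer
    than ``merge_max_gap_ms`` in time and ``merge_max_distance_deg`` in
    space only undoes splits.  Merged centroids are duration-weighted.
    """
    config = config or EventConfig()
    if not fixations:
        return []
    out = [fixations[0]]
    for f in fixations[1:]:
        prev = out[-1]
        gap_ms = (f.onset - prev.offset) * 1000.0
        dist = float(np.hypot(f.centroid_x - prev.centroid_x,
                              f.centroid_y - prev.centroid_y))
        if -0.5 <= gap_ms <= config.merge_max_gap_ms \
                and dist <= config.merge_max_distance_deg:
            w1, w2 = prev.duration, f.duration
            out[-1] = Fixation(
                onset=prev.onset, offset=f.offset,
                centroid_x=(prev.centroid_x * w1 + f.centroid_x * w2)
                / (w1 + w2),
                centroid_y=(prev.centroid_y * w1 + f.centroid_y * w2)
                / (w1 + w2),
            )
        else:
            out.append(f)
    return out


def detect_events(trial: Trial, config: EventConfig | None = None
                  ) -> OculomotorEvents:
    """Full event extraction for one trial (I-DT plus the merge post-step)."""
    config = config or EventConfig()
    blinks = detect_blinks(trial, config)
    fixations = merge_adjacent_fixations(
        detect_fixations_idt(trial, config), config)
    saccades = derive_saccades(fixations, trial, blinks, config)
    return OculomotorEvents(blinks=blinks, fixations=fixations,
                            saccades=saccades)
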