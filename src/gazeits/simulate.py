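"""Synthetic binocular gaze generator with planted oculomotor structure.

Each trial is rendered as an alternating chain of fixations and saccades:
fixations are a centroid plus Gaussian jitter and a slow linear drift,
saccades are minimum-jerk position ramps between centroids, and blinks are
inserted between fixations as runs of invalid samples followed by a landing
jump to a fresh centroid (so planted fixations never straddle a blink).
Binocular structure comes from a horizontal vergence process (slow AR(1)
disparity split symmetrically between the eyes) and the pupil channel is a
baseline plus slow AR(1) noise.

A binary condition effect is planted as multiplicative shifts on parameter
means (condition B at ``effect_size > 0`` has longer fixations, smaller and
fewer saccades, more blinks, larger vergence variability and a larger pupil);
``effect_size = 0`` makes both conditions generatively identical.  The shift
directions are illustrative of internally- vs externally-directed attention
reports in the literature, not a measured physiology.

Per-participant log-normal random effects on all means make person-dependent
and person-independent evaluation genuinely different.  Everything is
deterministic given the master seed: child streams are spawned per
participant and per trial by fixed-arithmetic seed sequences, so any subset
of the dataset is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .gaze_io import GazeRecording, Trial

__all__ = [
    "GeneratorConfig",
    "GroundTruthEvent",
    "SyntheticDataset",
    "generate_dataset",
    "preset",
    "PRESETS",
]


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All tunable parameters of the generator (units in field names)."""

    sampling_rate_hz: float = 250.0
    trial_length_s: float = 10.0
    n_participants: int = 10
    trials_per_participant: int = 96   # half per condition
    n_tasks: int = 1
    # fixations: log-normal durations truncated below
    fixation_duration_mean_ms: float = 260.0
    fixation_duration_sd_ms: float = 90.0
    fixation_duration_min_ms: float = 150.0
    fixation_jitter_sd_deg: float = 0.08
    drift_rate_deg_s: float = 0.3
    # saccades: gamma amplitudes with a floor (microsaccades out of scope)
    saccade_amplitude_mean_deg: float = 4.0
    saccade_amplitude_sd_deg: float = 1.5
    saccade_amplitude_min_deg: float = 2.0
    saccade_duration_base_ms: float = 25.0
    saccade_duration_per_deg_ms: float = 2.5
    # blinks
    blink_rate_per_min: float = 10.0
    blink_duration_mean_ms: float = 180.0
    blink_duration_sd_ms: float = 60.0
    blink_duration_min_ms: float = 80.0
    # binocular / pupil
    vergence_offset_mean_deg: float = 1.0
    vergence_offset_sd_deg: float = 0.3
    vergence_noise_sd_deg: float = 0.15
    pupil_baseline: float = 3.5
    pupil_sd: float = 0.35
    measurement_noise_sd_deg: float = 0.02
    # scanpath structure: condition A scans an ordered grid (stimulus-driven
    # viewing); condition B mixes in a random-walk centroid process with
    # probability clip(effect_size * delta_scan_disorder, 0, 1) per saccade
    scan_cols: int = 5
    scan_rows: int = 4
    scan_step_deg: float = 2.5
    scan_jitter_deg: float = 0.3
    # condition effect: multiplicative deltas applied to condition B means,
    # each scaled by effect_size (0 => identical generative laws)
    effect_size: float = 1.0
    delta_fixation_duration: float = 0.25
    delta_saccade_amplitude: float = -0.10
    delta_blink_rate: float = 0.25
    delta_vergence_noise: float = 0.30
    delta_pupil_baseline: float = 0.03
    delta_scan_disorder: float = 0.5
    # person-level heterogeneity (log-normal sigma on parameter means)
    participant_sd: float = 0.10
    field_half_extent_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_participant % 2 != 0:
            raise ConfigError("trials_per_participant must be even "
                              "(half per condition)")
        for name in ("sampling_rate_hz", "trial_length_s",
                     "fixation_duration_mean_ms", "saccade_amplitude_mean_deg",
                     "blink_rate_per_min", "blink_duration_mean_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.n_tasks < 1:
            raise ConfigError("n_tasks must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


PRESETS: dict[str, dict] = {
    # recording regimes of the three emulated studies
    "switch_like": dict(sampling_rate_hz=250.0, trial_length_s=10.0,
                        trials_per_participant=96, n_tasks=6),
    "align_like": dict(sampling_rate_hz=120.0, trial_length_s=15.0,
                       trials_per_participant=72, n_tasks=1),
    "pairs_like": dict(sampling_rate_hz=120.0, trial_length_s=20.0,
                       trials_per_participant=40, n_tasks=1),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Generator config emulating one of the three recording regimes."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class GroundTruthEvent:
    trial_id: str
    kind: str          # fixation | saccade | blink
    onset_s: float
    offset_s: float
    x: float = np.nan  # fixation centroid / saccade landing point
    y: float = np.nan


@dataclass
class SyntheticDataset:
    trials: list[Trial]
    ground_truth: list[GroundTruthEvent]
    config: GeneratorConfig

    def truth_for(self, trial_id: str, kind: str | None = None
                  ) -> list[GroundTruthEvent]:
        return [e for e in self.ground_truth
                if e.trial_id == trial_id and (kind is None or e.kind == kind)]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.ground_truth])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def _draw_lognormal(rng, mean, sd, minimum):
    mu, sigma = _lognormal_params(mean, sd)
    return max(minimum, float(rng.lognormal(mu, sigma)))


def _draw_gamma(rng, mean, sd, minimum):
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return max(minimum, float(rng.gamma(shape, scale)))


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _ar1(rng, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    from scipy.signal import lfilter

    innov_sd = sd * np.sqrt(1 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], eps)


@dataclass
class _TrialParams:
    fix_mean: float
    sacc_amp_mean: float
    blink_rate: float
    vergence_offset: float
    vergence_noise_sd: float
    pupil_baseline: float
    scan_disorder: float


def _participant_multipliers(cfg: GeneratorConfig, p_idx: int) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + p_idx]))
    names = ["fix", "sacc", "blink", "verg_off", "verg_sd", "pupil"]
    return {n: float(rng.lognormal(0.0, cfg.participant_sd)) for n in names}


def _condition_params(cfg: GeneratorConfig, mult: dict[str, float],
                      condition: str) -> _TrialParams:
    e = cfg.effect_size if condition == "B" else 0.0
    return _TrialParams(
        fix_mean=cfg.fixation_duration_mean_ms * mult["fix"]
        * (1 + e * cfg.delta_fixation_duration),
        sacc_amp_mean=max(cfg.saccade_amplitude_min_deg * 1.05,
                          cfg.saccade_amplitude_mean_deg * mult["sacc"]
                          * (1 + e * cfg.delta_saccade_amplitude)),
        blink_rate=cfg.blink_rate_per_min * mult["blink"]
        * (1 + e * cfg.delta_blink_rate),
        vergence_offset=cfg.vergence_offset_mean_deg * mult["verg_off"],
        vergence_noise_sd=cfg.vergence_noise_sd_deg * mult["verg_sd"]
        * (1 + e * cfg.delta_vergence_noise),
        pupil_baseline=cfg.pupil_baseline * mult["pupil"]
        * (1 + e * cfg.delta_pupil_baseline),
        scan_disorder=float(np.clip(e * cfg.delta_scan_disorder, 0.0, 1.0)),
    )


def _scan_grid(cfg: GeneratorConfig) -> np.ndarray:
    """Serpentine (boustrophedon) grid of stimulus positions, centred."""
    pts = []
    for r in range(cfg.scan_rows):
        cols = range(cfg.scan_cols)
        if r % 2 == 1:
            cols = reversed(list(cols))
        for c in cols:
            pts.append(((c - (cfg.scan_cols - 1) / 2) * cfg.scan_step_deg,
                        ((cfg.scan_rows - 1) / 2 - r) * cfg.scan_step_deg))
    return np.array(pts)


def _synthesize_trial(cfg: GeneratorConfig, params: _TrialParams,
                      rng: np.random.Generator, trial_id: str
                      ) -> tuple[GazeRecording, list[GroundTruthEvent]]:
    fs = cfg.sampling_rate_hz
    n = int(np.floor(cfg.trial_length_s * fs))
    length_s = n / fs
    half = cfg.field_half_extent_deg

    # --- segment chain in continuous time -------------------------------
    # each entry: (kind, duration_s, target_centroid)
    n_fix_est = max(1, length_s / ((params.fix_mean / 1000.0) + 0.04))
    expected_blinks = params.blink_rate * length_s / 60.0
    p_blink = min(0.8, expected_blinks / n_fix_est)

    grid = _scan_grid(cfg)
    scan_k = int(rng.integers(len(grid)))

    def grid_point(k: int) -> tuple[float, float]:
        gx0, gy0 = grid[k % len(grid)]
        return (float(gx0 + rng.normal(0, cfg.scan_jitter_deg)),
                float(gy0 + rng.normal(0, cfg.scan_jitter_deg)))

    def random_jump(pos: tuple[float, float]) -> tuple[float, float]:
        amp = _draw_gamma(rng, params.sacc_amp_mean,
                          cfg.saccade_amplitude_sd_deg,
                          cfg.saccade_amplitude_min_deg)
        # direction by rejection so the landing point stays on "screen"
        # and the planted amplitude is exact
        for _ in range(50):
            theta = rng.uniform(0, 2 * np.pi)
            nxt = (pos[0] + amp * np.cos(theta), pos[1] + amp * np.sin(theta))
            if abs(nxt[0]) <= half and abs(nxt[1]) <= half:
                return (float(nxt[0]), float(nxt[1]))
        theta = float(np.arctan2(-pos[1], -pos[0]))  # deep corner: aim centre
        return (float(pos[0] + amp * np.cos(theta)),
                float(pos[1] + amp * np.sin(theta)))

    segments: list[tuple[str, float, tuple[float, float]]] = []
    pos = grid_point(scan_k)
    t = 0.0
    # room needed after a fixation for one more saccade + detectable fixation
    tail_s = cfg.fixation_duration_min_ms / 1000.0 + 0.12
    while t < length_s:
        dur = _draw_lognormal(rng, params.fix_mean, cfg.fixation_duration_sd_ms,
                              cfg.fixation_duration_min_ms) / 1000.0
        if t + dur + tail_s >= length_s:
            # extend the final fixation to the trial end so no planted
            # fixation is truncated below detectability
            segments.append(("fixation", length_s - t, pos))
            break
        segments.append(("fixation", dur, pos))
        t += dur
        # structured stimulus scan vs internally-driven random walk
        if rng.uniform() < params.scan_disorder:
            nxt = random_jump(pos)
        else:
            # skip grid cells the gaze already sits on so consecutive
            # planted fixations stay separable
            for _ in range(len(grid)):
                scan_k += 1
                nxt = grid_point(scan_k)
                if np.hypot(nxt[0] - pos[0], nxt[1] - pos[1]) >= \
                        cfg.saccade_amplitude_min_deg * 0.75:
                    break
        if rng.uniform() < p_blink:
            bdur = _draw_lognormal(rng, cfg.blink_duration_mean_ms,
                                   cfg.blink_duration_sd_ms,
                                   cfg.blink_duration_min_ms) / 1000.0
            segments.append(("blink", bdur, nxt))
            t += bdur
        else:
            jump = float(np.hypot(nxt[0] - pos[0], nxt[1] - pos[1]))
            sdur = (cfg.saccade_duration_base_ms
                    + cfg.saccade_duration_per_deg_ms * jump) / 1000.0
            sdur = float(np.clip(sdur, 0.020, 0.080))
            segments.append(("saccade", sdur, nxt))
            t += sdur
        pos = nxt

    # --- render to the sample grid --------------------------------------
    ts = np.arange(n) / fs
    gx = np.empty(n)
    gy = np.empty(n)
    valid = np.ones(n, dtype=bool)
    truth: list[GroundTruthEvent] = []

    t0 = 0.0
    prev_end = segments[0][2]
    for kind, dur, target in segments:
        t1 = min(t0 + dur, length_s)
        idx = (ts >= t0) & (ts < t1)
        m = int(idx.sum())
        if m > 0:
            if kind == "fixation":
                theta_d = rng.uniform(0, 2 * np.pi)
                rel = ts[idx] - t0
                gx[idx] = (target[0]
                           + cfg.drift_rate_deg_s * rel * np.cos(theta_d)
                           + rng.normal(0, cfg.fixation_jitter_sd_deg, m))
                gy[idx] = (target[1]
                           + cfg.drift_rate_deg_s * rel * np.sin(theta_d)
                           + rng.normal(0, cfg.fixation_jitter_sd_deg, m))
                prev_end = (target[0] + cfg.drift_rate_deg_s
                            * (t1 - t0) * np.cos(theta_d),
                            target[1] + cfg.drift_rate_deg_s
                            * (t1 - t0) * np.sin(theta_d))
            elif kind == "saccade":
                tau = (ts[idx] - t0) / dur
                s = _min_jerk(np.clip(tau, 0, 1))
                gx[idx] = prev_end[0] + (target[0] - prev_end[0]) * s
                gy[idx] = prev_end[1] + (target[1] - prev_end[1]) * s
                prev_end = target
            else:  # blink: tracker loss; fill with last position, mark invalid
                gx[idx] = prev_end[0]
                gy[idx] = prev_end[1]
                valid[idx] = False
                prev_end = target
        if kind != "saccade" and m > 0:
            truth.append(GroundTruthEvent(trial_id, kind, t0, t1,
                                          target[0], target[1]))
        elif kind == "saccade":
            truth.append(GroundTruthEvent(trial_id, "saccade", t0, t1,
                                          target[0], target[1]))
        t0 = t1
        if t0 >= length_s:
            break

    # --- binocular split, pupil, measurement noise ----------------------
    v = params.vergence_offset + _ar1(rng, n, params.vergence_noise_sd, 0.95)
    noise = cfg.measurement_noise_sd_deg
    lx = gx + v / 2 + rng.normal(0, noise, n)
    rx = gx - v / 2 + rng.normal(0, noise, n)
    ly = gy + rng.normal(0, noise, n)
    ry = gy + rng.normal(0, noise, n)
    pupil_core = params.pupil_baseline + _ar1(rng, n, cfg.pupil_sd, 0.995)
    lp = pupil_core + rng.normal(0, 0.02, n)
    rp = pupil_core + rng.normal(0, 0.02, n)
    lp[~valid] = np.nan
    rp[~valid] = np.nan

    rec = GazeRecording(
        sampling_rate=fs, timestamps=ts,
        left_x=lx, left_y=ly, right_x=rx, right_y=ry,
        left_pupil=lp, right_pupil=rp, valid=valid, units="deg",
    )
    return rec, truth


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full dataset: every participant, exact class balance.

    Trials per participant alternate between conditions A and B in a seeded
    random order; task labels cycle so tasks partition the trials evenly.
    """
    trials: list[Trial] = []
    truth: list[GroundTruthEvent] = []
    for p_idx in range(config.n_participants):
        pid = f"p{p_idx:03d}"
        mult = _participant_multipliers(config, p_idx)
        n_tr = config.trials_per_participant
        conditions = np.array(["A", "B"]).repeat(n_tr // 2)
        order_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2000 + p_idx]))
        order_rng.shuffle(conditions)
        for t_idx in range(n_tr):
            trial_id = f"{pid}_t{t_idx:04d}"
            cond = str(conditions[t_idx])
            params = _condition_params(config, mult, cond)
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, p_idx, t_idx]))
            rec, ev = _synthesize_trial(config, params, rng, trial_id)
            trials.append(Trial(
                recording=rec, trial_id=trial_id, participant_id=pid,
                task_id=f"task{t_idx % config.n_tasks}", condition=cond,
            ))
            truth.extend(ev)
    return SyntheticDataset(trials=trials, ground_truth=truth, config=config)
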