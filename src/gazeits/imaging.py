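"""Imaging time series: GASF/GADF/MTF encodings and the per-trial panel.

A gaze coordinate series is rescaled to [-1, 1] and read as polar angles
``phi_i = arccos(x_i)`` with the timestamp as radius.  The Gramian angular
summation field is ``G_ij = cos(phi_i + phi_j)``, the difference field is
``G_ij = sin(phi_i - phi_j)``; both reduce to closed forms in the rescaled
values and never need the angles explicitly.  The Markov transition field
assigns each sample to one of ``Q`` quantile bins, estimates the first-order
bin-transition matrix ``W`` (row-stochastic), and spreads it over time:
``M_ij = W[bin(x_i), bin(x_j)]``, so the diagonal carries each time step's
self-transition probability.

Size reduction: the GAF inputs are shortened with piecewise aggregate
approximation (PAA) before encoding; the MTF is computed on the full
blink-filtered series and the *field* is then blurred by non-overlapping
patch averaging (computed without materializing the n x n matrix).  A config
switch lets the MTF use series-PAA instead, matching common reference
implementations.

One trial yields 12 images — 3 transforms x {left, right} x {X, Y} — exposed
both as a 12-channel stack (CNN input) and as the 3 x 4 tiled matrix, each
image min-max normalized to [-1, 1] independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .events import Blink
from .gaze_io import Trial

__all__ = [
    "FieldImage",
    "ImagePanel",
    "PanelConfig",
    "remove_blink_samples",
    "rescale_unit",
    "paa",
    "gasf",
    "gadf",
    "mtf",
    "mtf_reduced",
    "normalize_image",
    "build_image_panel",
    "gaze_heatmap",
]

PANEL_ROWS = ("mtf", "gasf", "gadf")
PANEL_COLS = ("left_x", "left_y", "right_x", "right_y")


class DegenerateInputError(ValueError):
    pass


@dataclass
class FieldImage:
    matrix: np.ndarray
    kind: str  # gasf | gadf | mtf | heatmap

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("field image must be square")

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


def remove_blink_samples(series: np.ndarray, blinks: Sequence[Blink],
                         timestamps: np.ndarray) -> np.ndarray:
    """Delete samples inside blink windows, concatenating the remainder."""
    series = np.asarray(series, dtype=float)
    keep = np.ones(len(series), dtype=bool)
    for b in blinks:
        keep &= ~((timestamps >= b.onset) & (timestamps < b.offset))
    out = series[keep]
    if len(out) < 2:
        raise DegenerateInputError("fewer than 2 samples remain after "
                                   "blink removal")
    return out


def rescale_unit(series: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1]; a constant series maps to all zeros."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("series must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def paa(series: np.ndarray, target_length: int) -> np.ndarray:
    """Piecewise aggregate approximation with fractional-boundary weighting.

    Each output value is the weighted mean of the samples overlapping its
    segment of the continuous index axis; exact segment means when the
    length divides evenly, identity when ``target_length == n``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    m = int(target_length)
    if not 1 <= m <= n:
        raise ValueError(f"target_length must be in [1, {n}]")
    if m == n:
        return x.copy()
    if n % m == 0:
        return x.reshape(m, n // m).mean(axis=1)
    out = np.empty(m)
    seg = n / m
    for i in range(m):
        a, b = i * seg, (i + 1) * seg
        j0, j1 = int(np.floor(a)), int(np.ceil(b))
        idx = np.arange(j0, min(j1, n))
        w = np.minimum(idx + 1, b) - np.maximum(idx, a)
        out[i] = float(np.dot(x[idx], w) / w.sum())
    return out


def _check_unit(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-9):
        raise ValueError("input must be rescaled to [-1, 1]")
    return np.clip(x, -1.0, 1.0)


def gasf(series: np.ndarray) -> FieldImage:
    """Gramian angular summation field: ``cos(phi_i + phi_j)``.

    Symmetric; diagonal equals ``2 x^2 - 1`` (the doubled angle of the
    original value).
    """
    x = _check_unit(series)
    s = np.sqrt(1.0 - x ** 2)
    return FieldImage(np.outer(x, x) - np.outer(s, s), "gasf")


def gadf(series: np.ndarray) -> FieldImage:
    """Gramian angular difference field: ``sin(phi_i - phi_j)``.

    Antisymmetric with a zero diagonal.
    """
    x = _check_unit(series)
    s = np.sqrt(1.0 - x ** 2)
    return FieldImage(np.outer(s, x) - np.outer(x, s), "gadf")


def _quantile_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Quantile bin index per sample; ties go to the lower bin.

    Returns ``(bins, q_effective)``; duplicate quantile edges are collapsed
    with a warning when the series has too few distinct values.
    """
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    edges = np.unique(edges)
    q_eff = len(edges) + 1
    if q_eff < n_bins or len(np.unique(x)) < n_bins:
        warnings.warn(f"series has fewer than {n_bins} distinct quantile "
                      "bins; collapsing", stacklevel=3)
    bins = np.searchsorted(edges, x, side="left")
    return bins, q_eff


def transition_matrix(series: np.ndarray, n_bins: int = 8
                      ) -> tuple[np.ndarray, np.ndarray]:
    """First-order quantile-bin transition matrix W (row-stochastic).

    Empty rows (bins never left) are set uniform.  Returns ``(W, bins)``.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    bins, q = _quantile_bins(x, n_bins)
    W = np.zeros((q, q))
    np.add.at(W, (bins[:-1], bins[1:]), 1.0)
    row = W.sum(axis=1, keepdims=True)
    uniform = row[:, 0] == 0
    W = np.divide(W, row, out=np.zeros_like(W), where=row > 0)
    W[uniform] = 1.0 / q
    return W, bins


def mtf(series: np.ndarray, n_bins: int = 8) -> FieldImage:
    """Full n x n Markov transition field ``M_ij = W[bin_i, bin_j]``."""
    W, bins = transition_matrix(series, n_bins)
    return FieldImage(W[np.ix_(bins, bins)], "mtf")


def _paa_weights(n: int, m: int) -> np.ndarray:
    """m x n row-normalized segment-membership weights (PAA as a matrix)."""
    A = np.zeros((m, n))
    seg = n / m
    for i in range(m):
        a, b = i * seg, (i + 1) * seg
        j0, j1 = int(np.floor(a)), min(int(np.ceil(b)), n)
        idx = np.arange(j0, j1)
        A[i, idx] = np.minimum(idx + 1, b) - np.maximum(idx, a)
    return A / A.sum(axis=1, keepdims=True)


def mtf_reduced(series: np.ndarray, n_bins: int = 8, size: int = 48,
                strategy: Literal["blur-field", "paa-series"] = "blur-field"
                ) -> FieldImage:
    """MTF at a reduced ``size`` x ``size`` resolution.

    ``blur-field`` computes the full-resolution field implicitly and
    patch-averages it (exactly, via the bin-membership aggregation
    ``(A B) W (A B)^T``); ``paa-series`` shortens the series first.
    """
    x = np.asarray(series, dtype=float)
    if strategy == "paa-series":
        return mtf(paa(x, size), n_bins)
    W, bins = transition_matrix(x, n_bins)
    q = W.shape[0]
    A = _paa_weights(len(x), size)
    B = np.zeros((len(x), q))
    B[np.arange(len(x)), bins] = 1.0
    AB = A @ B
    return FieldImage(AB @ W @ AB.T, "mtf")


def normalize_image(matrix: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [-1, 1]; constant -> zeros."""
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        return np.zeros_like(matrix)
    return 2.0 * (matrix - lo) / (hi - lo) - 1.0


@dataclass
class PanelConfig:
    image_size: int = 48            # one of 12, 24, 36, 48 in the sweeps
    mtf_bins: int = 8
    mtf_strategy: Literal["blur-field", "paa-series"] = "blur-field"

    def __post_init__(self) -> None:
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")


@dataclass
class ImagePanel:
    """12 normalized images for one trial, as stack and 3 x 4 tiling."""

    images: dict[tuple[str, str], np.ndarray]
    trial_id: str
    condition: str
    participant_id: str = ""
    task_id: str = ""

    @property
    def side(self) -> int:
        return next(iter(self.images.values())).shape[0]

    def stack(self) -> np.ndarray:
        """(12, s, s) channel stack ordered MTF, GASF, GADF x 4 channels."""
        return np.stack([self.images[(row, col)]
                         for row in PANEL_ROWS for col in PANEL_COLS])

    def tiled(self) -> np.ndarray:
        """(3s, 4s) tiled matrix: rows = transforms, columns = channels."""
        s = self.side
        out = np.empty((3 * s, 4 * s))
        for r, row in enumerate(PANEL_ROWS):
            for c, col in enumerate(PANEL_COLS):
                out[r * s:(r + 1) * s, c * s:(c + 1) * s] = self.images[(row, col)]
        return out

    @classmethod
    def from_tiled(cls, tiled: np.ndarray, side: int, **meta) -> "ImagePanel":
        """Inverse of :meth:`tiled` (layout is a bijection)."""
        images = {}
        for r, row in enumerate(PANEL_ROWS):
            for c, col in enumerate(PANEL_COLS):
                images[(row, col)] = tiled[r * side:(r + 1) * side,
                                           c * side:(c + 1) * side].copy()
        return cls(images=images, **meta)


def _channel_series(trial: Trial) -> dict[str, np.ndarray]:
    rec = trial.recording
    return {"left_x": rec.left_x, "left_y": rec.left_y,
            "right_x": rec.right_x, "right_y": rec.right_y}


def build_image_panel(trial: Trial, blinks: Sequence[Blink],
                      config: PanelConfig | None = None) -> ImagePanel:
    """Blink-filter each coordinate channel and encode the 12 images."""
    config = config or PanelConfig()
    s = config.image_size
    rec = trial.recording
    images: dict[tuple[str, str], np.ndarray] = {}
    for name, series in _channel_series(trial).items():
        filtered = remove_blink_samples(series, blinks, rec.timestamps)
        if len(filtered) < s:
            raise DegenerateInputError(
                f"channel {name}: {len(filtered)} samples after blink "
                f"removal, need >= {s}")
        reduced = rescale_unit(paa(filtered, s))
        images[("gasf", name)] = normalize_image(gasf(reduced).matrix)
        images[("gadf", name)] = normalize_image(gadf(reduced).matrix)
        m = mtf_reduced(filtered, config.mtf_bins, s, config.mtf_strategy)
        images[("mtf", name)] = normalize_image(m.matrix)
    return ImagePanel(images=images, trial_id=trial.trial_id,
                      condition=trial.condition,
                      participant_id=trial.participant_id,
                      task_id=trial.task_id)


def gaze_heatmap(trial: Trial, grid: int = 48,
                 extent: tuple[tuple[float, float], tuple[float, float]]
                 = ((-12.0, 12.0), (-12.0, 12.0))) -> FieldImage:
    """Occupancy histogram of the valid averaged gaze points.

    Mass-normalized to sum to 1, then min-max scaled to [-1, 1] so it can
    stand in for a panel as CNN input (spatial-information baseline).
    """
    (x0, x1), (y0, y1) = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate heatmap extent")
    rec = trial.recording
    if not rec.valid.any():
        raise DegenerateInputError("no valid samples for heatmap")
    gx, gy = rec.mean_gaze()
    H, _, _ = np.histogram2d(gx[rec.valid], gy[rec.valid], bins=grid,
                             range=[[x0, x1], [y0, y1]])
    total = H.sum()
    if total > 0:
        H = H / total
    return FieldImage(normalize_image(H), "heatmap")
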