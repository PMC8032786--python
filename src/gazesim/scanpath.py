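"""Scanpath encoding and pairwise similarity scoring.

A scanpath — the ordered sequence of fixations made while viewing a
stimulus — is recoded into a symbol sequence by binning fixation locations
on a rectangular region-of-interest grid (12 x 8 by default) and repeating
each location symbol once per temporal bin (50 ms by default) of the
fixation's duration.  Two such sequences are compared with the
Needleman-Wunsch global-alignment algorithm under a substitution matrix
whose score for a bin pair falls off linearly with the Euclidean distance
between bin centers and crosses zero at a threshold distance ``T`` (4 bins
by default), so the aligner only rewards matching regions at most ``T``
bins apart.  The raw alignment score is normalized by ``T`` times the
longer sequence length, giving a similarity score of 1 for identical
scanpaths and 0 for scanpaths with no spatial correspondence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import nw_score
from .config import StudyConfig

__all__ = [
    "Scanpath",
    "GridSpec",
    "assign_spatial_bin",
    "encode_sequence",
    "compute_substitution_threshold",
    "build_substitution_matrix",
    "nw_align",
    "similarity",
    "encode_scanpath",
    "scanpath_similarity",
]


@dataclass(frozen=True)
class Scanpath:
    """One viewing episode: ordered fixations of a (participant, trial, phase)."""

    participant_id: str
    trial_index: int
    phase: str
    x_px: np.ndarray
    y_px: np.ndarray
    duration_ms: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        d = np.asarray(self.duration_ms, dtype=float)
        if x.size == 0:
            raise ValueError("scanpath must contain at least one fixation")
        if not (x.size == y.size == d.size):
            raise ValueError("x, y and duration arrays must have equal length")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("fixation coordinates must be finite")
        if np.any(d <= 0):
            raise ValueError("fixation durations must be positive")
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)
        object.__setattr__(self, "duration_ms", d)

    def __len__(self) -> int:
        return self.x_px.size


@dataclass(frozen=True)
class GridSpec:
    """Rectangular bin grid over the stimulus; bins indexed row-major from 0."""

    nx: int = 12
    ny: int = 8
    stim_width_px: float = 1024.0
    stim_height_px: float = 768.0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one bin per axis")

    @property
    def bin_width_px(self) -> float:
        return self.stim_width_px / self.nx

    @property
    def bin_height_px(self) -> float:
        return self.stim_height_px / self.ny

    @property
    def n_bins(self) -> int:
        return self.nx * self.ny

    @classmethod
    def from_config(cls, config: StudyConfig) -> "GridSpec":
        return cls(config.grid_nx, config.grid_ny,
                   config.stim_width_px, config.stim_height_px)


def assign_spatial_bin(x_px, y_px, grid: GridSpec) -> np.ndarray | int:
    """Map stimulus coordinates to row-major bin indices.

    Off-stimulus coordinates clip to the nearest edge bin, so sequence
    length (and hence timing structure) is preserved for fixations that
    stray slightly outside the image.
    """
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("coordinates must be finite")
    col = np.clip(np.floor(x / grid.bin_width_px).astype(int), 0, grid.nx - 1)
    row = np.clip(np.floor(y / grid.bin_height_px).astype(int), 0, grid.ny - 1)
    out = row * grid.nx + col
    return int(out) if out.ndim == 0 else out


def encode_sequence(scanpath: Scanpath, grid: GridSpec,
                    temporal_bin_ms: float = 50.0,
                    max_length: int = 200) -> np.ndarray:
    """Expand a scanpath into its temporally binned symbol sequence.

    Each fixation contributes ``max(1, round(duration / temporal_bin))``
    repeats of its spatial-bin symbol, so even very short fixations keep a
    footprint in the sequence.  The result is truncated at ``max_length``
    symbols to bound alignment cost on pathological inputs.
    """
    if temporal_bin_ms <= 0:
        raise ValueError("temporal_bin_ms must be > 0")
    bins = np.atleast_1d(assign_spatial_bin(scanpath.x_px, scanpath.y_px, grid))
    repeats = np.maximum(1, np.round(scanpath.duration_ms / temporal_bin_ms).astype(int))
    seq = np.repeat(bins, repeats)
    return seq[:max_length].astype(np.int64)


def compute_substitution_threshold(saccade_amplitudes_px, grid: GridSpec) -> float:
    """Threshold from saccade statistics: twice the SD of gridded amplitudes.

    Amplitudes in pixels are expressed in horizontal-bin units
    (``amplitude / (stim_width / nx)``); the threshold is two sample
    standard deviations of that distribution.  The study's own analyses
    fix the threshold at 4 instead; this computation serves datasets with
    different geometry.
    """
    amp = np.asarray(saccade_amplitudes_px, dtype=float)
    if amp.size < 2:
        raise ValueError("need at least 2 saccade amplitudes")
    gridded = amp / grid.bin_width_px
    return float(2.0 * np.std(gridded, ddof=1))


def build_substitution_matrix(grid: GridSpec, threshold: float) -> np.ndarray:
    """Substitution scores ``s(a, b) = T - d(a, b)``.

    ``d`` is the Euclidean distance between bin (col, row) coordinates in
    bin units, so identical bins score ``T``, bins exactly ``T`` apart
    score 0, and more distant bins score negatively — the aligner only
    profits from aligning regions at most ``T`` bins apart.
    """
    if threshold <= 0:
        raise ValueError("substitution threshold must be > 0")
    idx = np.arange(grid.n_bins)
    col = idx % grid.nx
    row = idx // grid.nx
    d = np.hypot(col[:, None] - col[None, :], row[:, None] - row[None, :])
    return threshold - d


def nw_align(seq_a: np.ndarray, seq_b: np.ndarray, submatrix: np.ndarray,
             gap_penalty: float = 0.0) -> float:
    """Optimal global-alignment score (score only, no traceback)."""
    a = np.asarray(seq_a, dtype=np.int64)
    b = np.asarray(seq_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align an empty sequence")
    return nw_score(a, b, np.asarray(submatrix, dtype=float), float(gap_penalty))


def similarity(seq_a: np.ndarray, seq_b: np.ndarray, submatrix: np.ndarray,
               threshold: float, gap_penalty: float = 0.0) -> float:
    """Normalized similarity: raw score over ``T * max(|A|, |B|)``, in [0, 1].

    The denominator is the maximum attainable score (every symbol of the
    longer sequence substituted at distance zero), so identical sequences
    score exactly 1; with a zero gap penalty the raw score is never
    negative, so the lower bound is 0.
    """
    raw = nw_align(seq_a, seq_b, submatrix, gap_penalty)
    denom = threshold * max(len(seq_a), len(seq_b))
    return float(np.clip(raw / denom, 0.0, 1.0))


def encode_scanpath(scanpath: Scanpath, config: StudyConfig) -> np.ndarray:
    """Convenience: encode with grid/bin settings taken from a StudyConfig."""
    grid = GridSpec.from_config(config)
    return encode_sequence(scanpath, grid, config.temporal_bin_ms,
                           config.max_sequence_length)


def scanpath_similarity(a: Scanpath, b: Scanpath, config: StudyConfig) -> float:
    """End-to-end similarity of two scanpaths under a StudyConfig."""
    grid = GridSpec.from_config(config)
    sub = build_substitution_matrix(grid, config.substitution_threshold)
    ea = encode_scanpath(a, config)
    eb = encode_scanpath(b, config)
    return similarity(ea, eb, sub, config.substitution_threshold, config.gap_penalty)
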