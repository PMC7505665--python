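"""From 4-D runs to condition-average images.

Cleaning follows the common single-pass convention: the 24-parameter
motion expansion, per-outlier indicator columns, a linear trend and
discrete-cosine drift regressors (cutoff 128 s) are assembled into one
design matrix and regressed out of the time series simultaneously.  The
cleaned signal is then averaged within condition blocks after shifting
the averaging window by 3 TRs to account for the hemodynamic delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NuisanceDesign",
    "build_nuisance",
    "dct_drift_basis",
    "clean_timeseries",
    "average_blocks",
    "condition_average",
]


@dataclass
class NuisanceDesign:
    """Time x regressor nuisance matrix with column labels."""

    matrix: np.ndarray
    column_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("matrix columns must match labels")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


def build_nuisance(
    motion: np.ndarray, outlier_flags: np.ndarray | None = None
) -> NuisanceDesign:
    """Expand 6 motion parameters into the 24-column motion block.

    Columns: the 6 parameters, their squares, their backward differences
    (first row 0) and the squared differences — 24 motion-derived
    regressors — plus one indicator column per flagged outlier volume and
    a linear trend.
    """
    motion = np.asarray(motion, dtype=float)
    if isinstance(motion, np.ndarray) and motion.ndim != 2:
        raise ValueError("motion must be a time x 6 array")
    if motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion parameters, got {motion.shape[1]}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion values")
    n = motion.shape[0]

    diff = np.zeros_like(motion)
    diff[1:] = np.diff(motion, axis=0)
    blocks = [motion, motion**2, diff, diff**2]
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    labels = (
        [f"mot_{p}" for p in names]
        + [f"mot_{p}_sq" for p in names]
        + [f"mot_{p}_d" for p in names]
        + [f"mot_{p}_dsq" for p in names]
    )
    cols = np.hstack(blocks)

    if outlier_flags is not None:
        flags = np.asarray(outlier_flags, dtype=bool)
        if flags.shape != (n,):
            raise ValueError("outlier_flags must have one entry per volume")
        for t in np.flatnonzero(flags):
            ind = np.zeros((n, 1))
            ind[t, 0] = 1.0
            cols = np.hstack([cols, ind])
            labels.append(f"outlier_{t}")

    trend = np.linspace(-1.0, 1.0, n)[:, None]
    cols = np.hstack([cols, trend])
    labels.append("linear_trend")
    return NuisanceDesign(cols, labels)


def dct_drift_basis(n: int, tr_s: float, highpass_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift regressors with periods longer than the cutoff.

    Basis k (k >= 1) is cos(pi*k*(2t+1)/(2n)) with period 2*n*tr/k; all k
    with period > ``highpass_s`` are included.  May be empty for short runs.
    """
    if n < 2:
        raise ValueError("need at least 2 time points")
    k_max = int(np.floor(2.0 * n * tr_s / highpass_s))
    t = np.arange(n)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def clean_timeseries(
    ts: np.ndarray,
    design: NuisanceDesign | None,
    tr_s: float,
    highpass_s: float = 128.0,
) -> np.ndarray:
    """Regress nuisance design + DCT drift + intercept out of the signal.

    High-pass filtering is implemented by including the drift regressors in
    the same regression as the nuisance columns (single simultaneous pass).
    A rank-deficient design is handled by least squares on the pseudo-
    inverse, with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    n = ts.shape[0]
    parts = [np.ones((n, 1))]
    if design is not None:
        if design.n_timepoints != n:
            raise ValueError(
                f"design rows ({design.n_timepoints}) != time points ({n})"
            )
        parts.append(design.matrix)
    parts.append(dct_drift_basis(n, tr_s, highpass_s))
    x = np.hstack(parts)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    return ts - x @ beta


def average_blocks(
    ts: np.ndarray,
    onsets_s: np.ndarray,
    tr_s: float,
    duration_s: float = 16.0,
    shift_trs: int = 3,
) -> list[np.ndarray]:
    """Mean signal per block over the HRF-shifted averaging window.

    The block onset maps to the nearest earlier volume; the averaged
    window is ``[onset_vol + shift_trs, onset_vol + shift_trs +
    round(duration_s / tr_s))``.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    n = ts.shape[0]
    dur_vols = int(round(duration_s / tr_s))
    out = []
    for b, onset in enumerate(np.asarray(onsets_s, dtype=float)):
        i0 = int(np.floor(onset / tr_s)) + shift_trs
        i1 = i0 + dur_vols
        if i0 < 0 or i1 > n:
            raise ValueError(
                f"block {b} (onset {onset}s): shifted window [{i0}, {i1}) "
                f"exceeds run of {n} volumes"
            )
        out.append(ts[i0:i1].mean(axis=0))
    return out


def condition_average(
    block_vectors: list[np.ndarray], block_labels: list[str]
) -> dict[str, np.ndarray]:
    """Per-condition mean of its block vectors."""
    if len(block_vectors) != len(block_labels):
        raise ValueError("one label per block vector required")
    if not block_vectors:
        raise ValueError("no blocks given")
    out: dict[str, list[np.ndarray]] = {}
    for vec, lab in zip(block_vectors, block_labels):
        out.setdefault(lab, []).append(np.asarray(vec, dtype=float))
    return {lab: np.mean(vecs, axis=0) for lab, vecs in out.items()}
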