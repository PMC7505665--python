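"""Synthetic vicarious-pain fMRI data with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-subject condition-average images for two vicarious-pain
induction modalities (NS: observed noxious stimulation of limbs, FE:
painful facial expressions) with matched controls, a high-arousal
negative / neutral picture set, a six-level graded thermal-pain set with
subjective ratings, and raw block-design 4-D runs with motion-like
nuisance structure.

Each condition image is

    image(s, modality, condition) = subject_effect(s)
        + sum_k amplitude(condition, k) * pattern_k
        + N(0, noise_sd) per voxel

where the component patterns (shared pain, NS-unique, FE-unique, arousal)
have disjoint random supports, are mutually orthogonalized and unit
normalized.  Pain conditions load on the shared pattern, their own
modality-unique pattern and (weakly) the arousal pattern; negative
pictures load on the arousal pattern only; controls and neutral pictures
carry no condition signal.  The subject effect is a Gaussian intercept
image shared across all of a subject's conditions, which induces the
within-subject pairing that forced-choice evaluation exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from nilearn.glm.first_level import glover_hrf

from .grid import VolumeGrid, make_grid

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "make_grid",
    "default_effect_sizes",
    "plant_patterns",
    "simulate_subjects",
    "simulate_thermal",
    "simulate_run",
]

COMPONENTS = ("shared", "ns_unique", "fe_unique", "arousal")

EMPATHY_CELLS = [
    ("NS", "pain"),
    ("NS", "control"),
    ("FE", "pain"),
    ("FE", "control"),
    ("IAPS", "negative"),
    ("IAPS", "neutral"),
]


def default_effect_sizes(
    shared: float = 1.5,
    unique: float = 0.8,
    arousal_on_pain: float = 0.4,
    arousal_on_negative: float = 1.5,
) -> dict[str, dict[str, float]]:
    """Condition -> component amplitude map.

    Amplitudes are in units of the voxel noise sd.  The defaults place
    the generator in the qualitative regime the analyses target: strong
    within-modality decodability, intermediate between-modality transfer
    (the shared component outweighs the unique ones), and weak arousal
    leakage into the pain conditions.
    """
    return {
        "NS-pain": {"shared": shared, "ns_unique": unique, "arousal": arousal_on_pain},
        "NS-control": {},
        "FE-pain": {"shared": shared, "fe_unique": unique, "arousal": arousal_on_pain},
        "FE-control": {},
        "IAPS-negative": {"arousal": arousal_on_negative},
        "IAPS-neutral": {},
    }


@dataclass
class GroundTruth:
    """Planted component patterns and generative parameters."""

    grid: VolumeGrid
    shared_pattern: np.ndarray
    ns_unique_pattern: np.ndarray
    fe_unique_pattern: np.ndarray
    arousal_pattern: np.ndarray
    effect_sizes: dict[str, dict[str, float]]
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    seed: int | None = None

    def pattern(self, component: str) -> np.ndarray:
        return getattr(self, f"{component}_pattern")

    @property
    def is_null(self) -> bool:
        """True when no component carries any signal (null truth)."""
        return all(
            not np.any(self.pattern(c)) for c in COMPONENTS
        )

    def condition_mean(self, key: str) -> np.ndarray:
        """Noise-free expected image for a condition key like ``"NS-pain"``."""
        out = np.zeros(self.grid.n_voxels)
        for comp, amp in self.effect_sizes.get(key, {}).items():
            out += amp * self.pattern(comp)
        return out

    def with_effects(self, effect_sizes: dict[str, dict[str, float]]) -> "GroundTruth":
        return replace(self, effect_sizes=effect_sizes)


@dataclass
class SyntheticDataset:
    """Condition images plus their design table and the generating truth.

    ``images`` rows align with ``design`` rows; columns are the masked
    voxel vector of ``grid``.  ``design`` has columns subject, modality,
    condition and, for thermal data, level and rating.
    """

    grid: VolumeGrid
    images: np.ndarray
    design: pd.DataFrame
    truth: GroundTruth | None = None

    def __post_init__(self):
        if self.images.shape[0] != len(self.design):
            raise ValueError("images rows must match design rows")
        if self.images.shape[1] != self.grid.n_voxels:
            raise ValueError("image vectors must have mask length")

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.design["subject"].to_numpy())

    def select(self, modality: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """(subjects, images) for one modality x condition cell, subject-sorted."""
        sel = (self.design["modality"] == modality) & (
            self.design["condition"] == condition
        )
        sub = self.design.loc[sel, "subject"].to_numpy()
        order = np.argsort(sub, kind="stable")
        return sub[order], self.images[np.flatnonzero(sel)[order]]

    def paired(
        self, modality: str, condition_pos: str, condition_neg: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Subject-aligned (subjects, positive images, negative images)."""
        s_pos, img_pos = self.select(modality, condition_pos)
        s_neg, img_neg = self.select(modality, condition_neg)
        common, i_pos, i_neg = np.intersect1d(s_pos, s_neg, return_indices=True)
        if common.size == 0:
            raise ValueError(
                f"no subjects with both {condition_pos} and {condition_neg} "
                f"in modality {modality}"
            )
        return common, img_pos[i_pos], img_neg[i_neg]

    def to_dir(self, out_dir: str | Path) -> None:
        """Write volumes (.nii.gz), a design TSV and a truth JSON sidecar."""
        from . import io as srio  # local import to avoid a cycle

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        srio.write_volume(self.grid.mask.astype(np.int8), self.grid, out_dir / "mask.nii.gz")
        paths = []
        for i in range(self.images.shape[0]):
            row = self.design.iloc[i]
            name = f"sub-{row['subject']:03d}_{row['modality']}_{row['condition']}.nii.gz"
            srio.write_volume(self.grid.to_volume(self.images[i]), self.grid, out_dir / name)
            paths.append(name)
        design = self.design.copy()
        design["path"] = paths
        design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
        if self.truth is not None:
            truth = {
                "effect_sizes": self.truth.effect_sizes,
                "noise_sd": self.truth.noise_sd,
                "subject_sd": self.truth.subject_sd,
                "seed": self.truth.seed,
                "components": {
                    c: self.truth.pattern(c).tolist() for c in COMPONENTS
                },
            }
            (out_dir / "truth.json").write_text(json.dumps(truth))


def plant_patterns(
    grid: VolumeGrid,
    n_shared: int,
    n_ns: int,
    n_fe: int,
    n_arousal: int,
    seed: int | None = None,
    effect_sizes: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 1.0,
    subject_sd: float = 0.5,
) -> GroundTruth:
    """Plant component patterns on disjoint random voxel supports.

    Support sizes are taken verbatim; the four components are then
    Gram-Schmidt orthogonalized in the order shared, NS-unique, FE-unique,
    arousal and unit-normalized.  Disjoint supports already make them
    orthogonal, so orthogonalization only matters if a caller later mixes
    patterns.  All-zero counts yield an explicit null truth
    (:attr:`GroundTruth.is_null`).
    """
    counts = [int(n) for n in (n_shared, n_ns, n_fe, n_arousal)]
    if any(c < 0 for c in counts):
        raise ValueError("support sizes must be nonnegative")
    if sum(counts) > grid.n_voxels:
        raise ValueError(
            f"requested supports ({sum(counts)}) exceed mask size ({grid.n_voxels})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(grid.n_voxels)
    patterns = []
    start = 0
    for c in counts:
        vec = np.zeros(grid.n_voxels)
        support = perm[start : start + c]
        # signed weights: shared-positive and shared-negative voxels both occur
        vec[support] = rng.normal(size=c)
        # guard against a degenerate all-zero draw on a nonempty support
        while c > 0 and not np.any(vec):
            vec[support] = rng.normal(size=c)
        patterns.append(vec)
        start += c
    # Gram-Schmidt in fixed order, then unit norm
    ortho: list[np.ndarray] = []
    for vec in patterns:
        v = vec.copy()
        for u in ortho:
            nu = np.dot(u, u)
            if nu > 0:
                v -= (np.dot(v, u) / nu) * u
        ortho.append(v)
    out = []
    for v in ortho:
        n = np.linalg.norm(v)
        out.append(v / n if n > 0 else v)
    return GroundTruth(
        grid=grid,
        shared_pattern=out[0],
        ns_unique_pattern=out[1],
        fe_unique_pattern=out[2],
        arousal_pattern=out[3],
        effect_sizes=dict(effect_sizes) if effect_sizes is not None else default_effect_sizes(),
        noise_sd=float(noise_sd),
        subject_sd=float(subject_sd),
        seed=seed,
    )


def simulate_subjects(
    truth: GroundTruth, n_subjects: int, seed: int | None = None
) -> SyntheticDataset:
    """Draw one condition-average image per subject per design cell.

    Cells: NS-pain, NS-control, FE-pain, FE-control, IAPS-negative,
    IAPS-neutral (six images per subject).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    v = truth.grid.n_voxels
    rows, images = [], []
    for s in range(n_subjects):
        subject_effect = rng.normal(0.0, truth.subject_sd, size=v)
        for modality, condition in EMPATHY_CELLS:
            mean = truth.condition_mean(f"{modality}-{condition}")
            noise = (
                rng.normal(0.0, truth.noise_sd, size=v) if truth.noise_sd > 0 else 0.0
            )
            images.append(subject_effect + mean + noise)
            rows.append({"subject": s, "modality": modality, "condition": condition})
    return SyntheticDataset(
        grid=truth.grid,
        images=np.asarray(images),
        design=pd.DataFrame(rows),
        truth=truth,
    )


def simulate_thermal(
    truth: GroundTruth,
    n_subjects: int = 33,
    n_levels: int = 6,
    slope: float = 0.75,
    rating_noise: float = 1.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Graded-intensity dataset: one image per subject per stimulation level.

    Level k (1-based) loads ``slope * k`` on the shared pain pattern; the
    per-subject rating is linear in level plus Gaussian noise of sd
    ``rating_noise`` — the simplest monotone stimulus-response model the
    correlation analyses require.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if rating_noise < 0:
        raise ValueError("rating_noise must be nonnegative")
    rng = np.random.default_rng(seed)
    v = truth.grid.n_voxels
    rows, images = [], []
    for s in range(n_subjects):
        subject_effect = rng.normal(0.0, truth.subject_sd, size=v)
        for level in range(1, n_levels + 1):
            noise = (
                rng.normal(0.0, truth.noise_sd, size=v) if truth.noise_sd > 0 else 0.0
            )
            images.append(
                subject_effect + slope * level * truth.shared_pattern + noise
            )
            rating = level + (
                rng.normal(0.0, rating_noise) if rating_noise > 0 else 0.0
            )
            rows.append(
                {
                    "subject": s,
                    "modality": "THERMAL",
                    "condition": f"level-{level}",
                    "level": level,
                    "rating": rating,
                }
            )
    return SyntheticDataset(
        grid=truth.grid,
        images=np.asarray(images),
        design=pd.DataFrame(rows),
        truth=truth,
    )


BLOCK_DURATION_S = 16.0


def simulate_run(
    truth: GroundTruth,
    block_onsets_s: list[float],
    block_labels: list[str],
    tr_s: float = 2.0,
    n_volumes: int = 200,
    motion_sd: float = 0.1,
    seed: int | None = None,
    drift_amplitude: float = 1.0,
    motion_coupling: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Block-design 4-D run (as time x masked-voxel matrix) + motion table.

    Each 16-s block's boxcar is convolved with the canonical (Glover)
    hemodynamic response and projects the block condition's mean pattern
    into voxel space.  Slow cosine drift (amplitude ``drift_amplitude``),
    a motion-coupled nuisance signal (random-walk motion parameters times
    random voxel loadings, scaled by ``motion_coupling``) and white noise
    of sd ``truth.noise_sd`` are added.  Returns the time series and a
    6-column motion parameter table.
    """
    if len(block_onsets_s) != len(block_labels):
        raise ValueError("one label per onset required")
    onsets = np.asarray(block_onsets_s, dtype=float)
    if np.any(onsets < 0):
        raise ValueError("onsets must be nonnegative")
    run_len = n_volumes * tr_s
    if np.any(onsets + BLOCK_DURATION_S > run_len):
        raise ValueError("all blocks (onset + 16 s) must fit inside the run")
    order = np.argsort(onsets)
    if np.any(np.diff(onsets[order]) < BLOCK_DURATION_S):
        raise ValueError("overlapping blocks")

    rng = np.random.default_rng(seed)
    v = truth.grid.n_voxels
    t = np.arange(n_volumes) * tr_s

    # condition signal: per-condition convolved boxcar times its mean pattern
    hrf = glover_hrf(tr_s, oversampling=1)
    ts = np.zeros((n_volumes, v))
    for cond in sorted(set(block_labels)):
        boxcar = np.zeros(n_volumes)
        for onset, lab in zip(onsets, block_labels):
            if lab != cond:
                continue
            i0 = int(np.floor(onset / tr_s))
            i1 = int(np.floor((onset + BLOCK_DURATION_S) / tr_s))
            boxcar[i0:i1] = 1.0
        conv = np.convolve(boxcar, hrf)[:n_volumes]
        ts += np.outer(conv, truth.condition_mean(cond))

    # slow drift: lowest two cosine harmonics with random amplitudes
    if drift_amplitude > 0:
        for k in (1, 2):
            basis = np.cos(np.pi * k * (t + tr_s / 2) / run_len)
            ts += np.outer(
                drift_amplitude * rng.normal(size=1) * basis, rng.normal(size=v)
            )

    # random-walk motion parameters + motion-coupled voxel signal
    motion = np.cumsum(rng.normal(0.0, motion_sd, size=(n_volumes, 6)), axis=0)
    if motion_coupling > 0 and motion_sd > 0:
        ts += motion_coupling * motion @ rng.normal(0.0, 1.0, size=(6, v))

    if truth.noise_sd > 0:
        ts += rng.normal(0.0, truth.noise_sd, size=(n_volumes, v))

    motion_table = pd.DataFrame(
        motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
    )
    return ts, motion_table
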