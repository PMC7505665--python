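"""Local-pattern (searchlight) within- and between-modality decoding.

For every in-mask centre voxel, the decoder features are restricted to a
spherical neighbourhood and four accuracy maps are produced: within-
modality cross-validation for each modality and between-modality
cross-prediction in both directions.  The same subject-to-fold partition
is reused across centres so that centre-to-centre differences reflect
local information, not fold luck.  Centre significance is a subject-level
binomial test of the pooled forced-choice outcomes; each map is FDR-
corrected across centres and the conjunction keeps centres significant
on all four maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decode import CVScheme, _binom_p_greater, _cv_arrays
from .grid import VolumeGrid
from .patstats import fdr_threshold
from .simulate import SyntheticDataset

__all__ = ["SearchlightMap", "sphere_offsets", "sphere_indices", "searchlight_crosspred"]


@dataclass
class SearchlightMap:
    """Per-centre accuracy and p maps over the mask, plus the conjunction."""

    grid: VolumeGrid
    radius: dict
    accuracy: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    significant: dict[str, np.ndarray] = field(default_factory=dict)
    conjunction: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def sphere_offsets(
    voxel_size_mm: tuple[float, float, float],
    radius_voxels: float | None = None,
    radius_mm: float | None = None,
) -> np.ndarray:
    """Integer lattice offsets within the requested Euclidean radius.

    Exactly one of ``radius_voxels`` (isotropic voxel units) or
    ``radius_mm`` (physical units, via the voxel size) must be given.
    """
    if (radius_voxels is None) == (radius_mm is None):
        raise ValueError("give exactly one of radius_voxels or radius_mm")
    if radius_voxels is not None:
        if radius_voxels < 0:
            raise ValueError("radius must be nonnegative")
        r = float(radius_voxels)
        scale = np.ones(3)
        rmax = np.full(3, int(np.floor(r)))
    else:
        if radius_mm < 0:
            raise ValueError("radius must be nonnegative")
        r = float(radius_mm)
        scale = np.asarray(voxel_size_mm, dtype=float)
        rmax = np.floor(r / scale).astype(int)
    axes = [np.arange(-m, m + 1) for m in rmax]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    d2 = (dx * scale[0]) ** 2 + (dy * scale[1]) ** 2 + (dz * scale[2]) ** 2
    keep = d2 <= r**2 + 1e-9
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_indices(
    grid: VolumeGrid,
    center: tuple[int, int, int],
    radius_voxels: float | None = None,
    radius_mm: float | None = None,
) -> np.ndarray:
    """Masked-vector indices of the sphere around a centre voxel.

    Sphere voxels falling outside the grid or outside the mask are
    dropped (no padding).  The centre must itself be in the mask.
    """
    center = np.asarray(center, dtype=int)
    if center.shape != (3,):
        raise ValueError("center must be a voxel triple")
    if (
        np.any(center < 0)
        or np.any(center >= np.asarray(grid.shape))
        or not grid.mask[tuple(center)]
    ):
        raise ValueError(f"center {tuple(center)} is outside the mask")
    offsets = sphere_offsets(grid.voxel_size_mm, radius_voxels, radius_mm)
    pts = center[None, :] + offsets
    ok = np.all((pts >= 0) & (pts < np.asarray(grid.shape)), axis=1)
    pts = pts[ok]
    lookup = _masked_index_volume(grid)
    idx = lookup[pts[:, 0], pts[:, 1], pts[:, 2]]
    return np.sort(idx[idx >= 0])


def _masked_index_volume(grid: VolumeGrid) -> np.ndarray:
    """3-D lattice of each voxel's position in the masked vector (-1 outside)."""
    vol = np.full(grid.shape, -1, dtype=np.int64)
    coords = grid.mask_coords
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(grid.n_voxels)
    return vol


def searchlight_crosspred(
    dataset: SyntheticDataset,
    modalities: tuple[str, str] = ("NS", "FE"),
    radius_voxels: float | None = 3.0,
    radius_mm: float | None = None,
    scheme: CVScheme | None = None,
    q: float = 0.05,
    C: float = 1.0,
    conditions: tuple[str, str] = ("pain", "control"),
) -> SearchlightMap:
    """Within- and between-modality accuracy maps over spherical regions.

    Returns maps keyed ``within_A``, ``within_B``, ``between_AtoB`` and
    ``between_BtoA`` (A, B = the two modalities).  Decoder failures at a
    centre (degenerate local data) leave that centre at chance with p = 1
    rather than aborting the map.
    """
    mod_a, mod_b = modalities
    if scheme is None:
        scheme = CVScheme(n_folds=10, n_repeats=1, seed=0)
    grid = dataset.grid
    subs_a, pain_a, ctrl_a = dataset.paired(mod_a, *conditions)
    subs_b, pain_b, ctrl_b = dataset.paired(mod_b, *conditions)
    if not np.array_equal(subs_a, subs_b):
        raise ValueError("both modalities must cover the same subjects")
    assignments = scheme.assignments(pain_a.shape[0])

    keys = [
        f"within_{mod_a}",
        f"within_{mod_b}",
        f"between_{mod_a}to{mod_b}",
        f"between_{mod_b}to{mod_a}",
    ]
    jobs = {
        keys[0]: (pain_a, ctrl_a, pain_a, ctrl_a),
        keys[1]: (pain_b, ctrl_b, pain_b, ctrl_b),
        keys[2]: (pain_a, ctrl_a, pain_b, ctrl_b),
        keys[3]: (pain_b, ctrl_b, pain_a, ctrl_a),
    }
    n_centers = grid.n_voxels
    accuracy = {k: np.full(n_centers, 0.5) for k in keys}
    pmaps = {k: np.ones(n_centers) for k in keys}

    coords = grid.mask_coords
    offsets = sphere_offsets(grid.voxel_size_mm, radius_voxels, radius_mm)
    lookup = _masked_index_volume(grid)
    shape = np.asarray(grid.shape)
    n_subj = pain_a.shape[0]
    for c in range(n_centers):
        pts = coords[c][None, :] + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        feat = lookup[pts[:, 0], pts[:, 1], pts[:, 2]]
        feat = feat[feat >= 0]
        for key, (tp, tc, ep, ec) in jobs.items():
            try:
                res = _cv_arrays(
                    tp[:, feat], tc[:, feat], ep[:, feat], ec[:, feat],
                    assignments, C=C,
                )
            except Exception:  # degenerate local data: leave centre at chance
                continue
            accuracy[key][c] = res.accuracy_2afc
            # subject-level binomial on pooled outcomes, averaged over repeats
            wins = int(round(np.sum(res.per_subject_correct > 0.5)))
            pmaps[key][c] = _binom_p_greater(wins, n_subj)

    significant = {k: fdr_threshold(pmaps[k], q=q) for k in keys}
    conj = np.logical_and.reduce([significant[k] for k in keys])
    return SearchlightMap(
        grid=grid,
        radius={"voxels": radius_voxels} if radius_mm is None else {"mm": radius_mm},
        accuracy=accuracy,
        p=pmaps,
        significant=significant,
        conjunction=conj,
    )
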