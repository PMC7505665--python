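"""Map-level statistics on masked voxel vectors.

Group t-maps with Benjamini-Hochberg FDR and cluster-extent filtering,
conjunction masks, spatial similarity with a within-subject label-
permutation test, bootstrap reliability maps of decoder weights, and the
octant joint-weight decomposition of two weight maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .decode import fit_pattern
from .grid import VolumeGrid

__all__ = [
    "ResampleMap",
    "OctantSummary",
    "group_ttest",
    "fdr_threshold",
    "extent_filter",
    "conjunction",
    "spatial_correlation",
    "permutation_similarity",
    "PermutationResult",
    "bootstrap_weights",
    "octant_analysis",
]


@dataclass
class ResampleMap:
    """Per-voxel statistic map with p-values and a thresholded mask."""

    stat: np.ndarray
    p: np.ndarray
    thresholded_mask: np.ndarray
    method: str
    n_samples: int
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def group_ttest(contrasts: np.ndarray) -> ResampleMap:
    """Voxel-wise one-sample t-test of subject contrast images against 0.

    Zero-variance voxels get t = 0, p = 1 and are flagged.  Two-tailed p
    from the t distribution with n-1 degrees of freedom.
    """
    x = np.asarray(contrasts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a subjects x voxels array with >= 3 subjects")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0
    t = np.zeros(x.shape[1])
    np.divide(mean, sd / np.sqrt(n), out=t, where=~zero_var)
    p = np.ones(x.shape[1])
    p[~zero_var] = 2.0 * stats.t.sf(np.abs(t[~zero_var]), df=n - 1)
    return ResampleMap(
        stat=t,
        p=p,
        thresholded_mask=np.zeros(x.shape[1], dtype=bool),
        method="ttest",
        n_samples=n,
        zero_variance=zero_var,
    )


def fdr_threshold(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at level q."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def extent_filter(
    mask: np.ndarray, grid: VolumeGrid, min_mm3: float = 100.0
) -> np.ndarray:
    """Drop connected components smaller than the minimum extent.

    Components are defined by 18-connectivity (faces + edges); a component
    is removed when voxel count x voxel volume is strictly below
    ``min_mm3`` (at 2 mm isotropic: 12-voxel clusters go, 13-voxel stay).
    Accepts a 3-D lattice or a masked vector; returns the same form.
    """
    arr = np.asarray(mask, dtype=bool)
    as_vector = arr.ndim == 1
    vol = grid.to_volume(arr.astype(float)).astype(bool) if as_vector else arr
    if vol.shape != grid.shape:
        raise ValueError("mask does not match grid")
    structure = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
    labels, n = ndimage.label(vol, structure=structure)
    if n:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts * grid.voxel_volume_mm3 < min_mm3)
        small = small[small > 0]
        vol = vol & ~np.isin(labels, small)
    return grid.to_masked(vol.astype(float)).astype(bool) if as_vector else vol


def conjunction(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    stat_a: np.ndarray | None = None,
    stat_b: np.ndarray | None = None,
    require_same_sign: bool = False,
) -> np.ndarray:
    """Elementwise AND of two masks, optionally sign-consistent."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    out = a & b
    if require_same_sign:
        if stat_a is None or stat_b is None:
            raise ValueError("sign consistency requires both stat maps")
        out = out & (np.sign(stat_a) == np.sign(stat_b)) & (np.sign(stat_a) != 0)
    return out


def spatial_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two maps over the (optionally masked) voxels."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must align")
    if mask is not None:
        a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValueError("need at least 3 common voxels")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class PermutationResult:
    r_obs: float
    p: float
    p_perm_a: float
    p_perm_b: float
    null: np.ndarray = field(repr=False)
    n_perm: int = 0
    alternative: str = "two-sided"


def _swap_pairs(
    pain: np.ndarray, ctrl: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle condition labels within subject (random pairwise swaps)."""
    swap = rng.random(pain.shape[0]) < 0.5
    new_pain = np.where(swap[:, None], ctrl, pain)
    new_ctrl = np.where(swap[:, None], pain, ctrl)
    return new_pain, new_ctrl


def permutation_similarity(
    pair_a: tuple[np.ndarray, np.ndarray],
    pair_b: tuple[np.ndarray, np.ndarray],
    map_builder,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Label-permutation test of the spatial similarity of two group maps.

    ``map_builder(pain, control) -> masked vector`` builds a group map
    (t-map or decoder weights) from subject-aligned condition images.  The
    null pools two shuffle directions: condition labels are swapped within
    subject for dataset A (map correlated against the true B map) and,
    separately, for dataset B — ``n_perm`` permutations per side.  The
    add-one rule p = (1 + #{null >= observed}) / (1 + 2 n_perm) avoids
    p = 0; 'two-sided' compares |r|, 'greater' compares signed r.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations per side; p is coarse")
    rng = np.random.default_rng(seed)
    map_a = np.asarray(map_builder(*pair_a), dtype=float)
    map_b = np.asarray(map_builder(*pair_b), dtype=float)
    r_obs = spatial_correlation(map_a, map_b)
    null = np.empty(2 * n_perm)
    for i in range(n_perm):
        pa = _swap_pairs(*pair_a, rng)
        null[i] = spatial_correlation(np.asarray(map_builder(*pa)), map_b)
    for i in range(n_perm):
        pb = _swap_pairs(*pair_b, rng)
        null[n_perm + i] = spatial_correlation(map_a, np.asarray(map_builder(*pb)))

    def add_one(vals: np.ndarray, obs: float) -> float:
        if alternative == "two-sided":
            hits = int(np.sum(np.abs(vals) >= abs(obs)))
        elif alternative == "greater":
            hits = int(np.sum(vals >= obs))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return (1 + hits) / (1 + vals.size)

    return PermutationResult(
        r_obs=r_obs,
        p=add_one(null, r_obs),
        p_perm_a=add_one(null[:n_perm], r_obs),
        p_perm_b=add_one(null[n_perm:], r_obs),
        null=null,
        n_perm=n_perm,
        alternative=alternative,
    )


def ttest_map_builder(pain: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Group t-map of the paired pain-minus-control contrast."""
    return group_ttest(pain - ctrl).stat


def svm_weight_builder(C: float = 1.0):
    """Decoder-weight map builder for permutation / bootstrap resampling."""

    def build(pain: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
        x = np.vstack([pain, ctrl])
        y = np.concatenate([np.ones(pain.shape[0]), -np.ones(ctrl.shape[0])])
        return fit_pattern(x, y, C=C).weights

    return build


def bootstrap_weights(
    pain: np.ndarray,
    ctrl: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    builder=None,
    grid: VolumeGrid | None = None,
    q: float = 0.05,
    min_mm3: float = 100.0,
) -> ResampleMap:
    """Bootstrap reliability map of decoder weights.

    Subjects are resampled with replacement ``n_boot`` times; the decoder
    is retrained per sample and per-voxel z = mean(w*) / sd(w*) summarizes
    reliability, with two-tailed normal p.  The thresholded mask applies
    BH-FDR at ``q`` and, when a grid is supplied, the minimum cluster
    extent.  Voxels with zero bootstrap sd get p = 1 when their mean is 0
    and are flagged extreme (p -> 0) otherwise.
    """
    pain = np.asarray(pain, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    n_subj = pain.shape[0]
    if n_subj < 10:
        raise ValueError("need at least 10 subjects to bootstrap")
    if builder is None:
        builder = svm_weight_builder()
    rng = np.random.default_rng(seed)
    acc = np.zeros(pain.shape[1])
    acc2 = np.zeros(pain.shape[1])
    for _ in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        # a bootstrap draw of one repeated subject has no class contrast;
        # resample until both sides vary (measure-zero event for n >= 10)
        while np.unique(idx).size < 2:
            idx = rng.integers(0, n_subj, size=n_subj)
        w = np.asarray(builder(pain[idx], ctrl[idx]), dtype=float)
        acc += w
        acc2 += w * w
    mean = acc / n_boot
    var = np.maximum(acc2 / n_boot - mean**2, 0.0)
    sd = np.sqrt(var * n_boot / max(n_boot - 1, 1))
    zero_sd = sd == 0
    z = np.zeros_like(mean)
    np.divide(mean, sd, out=z, where=~zero_sd)
    z[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * np.inf
    p = np.ones_like(mean)
    finite = np.isfinite(z) & ~zero_sd
    p[finite] = 2.0 * stats.norm.sf(np.abs(z[finite]))
    p[np.isinf(z)] = np.nextafter(0, 1)
    thr = fdr_threshold(np.clip(p, np.nextafter(0, 1), 1.0), q=q)
    if grid is not None:
        thr = extent_filter(thr, grid, min_mm3=min_mm3)
    return ResampleMap(
        stat=z,
        p=p,
        thresholded_mask=thr,
        method="bootstrap",
        n_samples=n_boot,
        zero_variance=zero_sd,
    )


@dataclass
class OctantSummary:
    """Joint-weight octant decomposition of two z-scored weight maps.

    Octant semantics with map X on the x-axis and map Y on the y-axis
    (sectors are 45 degrees wide, centred on the axes and diagonals):
    O1 +y selective, O2 shared positive, O3 +x selective, O4 +x/-y,
    O5 -y selective, O6 shared negative, O7 -x selective, O8 -x/+y.
    """

    counts: np.ndarray
    ssd: np.ndarray
    excluded_zero: int
    octant_of: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# maps floor((theta - 67.5) / 45) mod 8 to the octant number
_OCTANT_LOOKUP = np.array([1, 8, 7, 6, 5, 4, 3, 2])


def octant_analysis(w_x: np.ndarray, w_y: np.ndarray) -> OctantSummary:
    """Assign voxels to the eight equal angular octants of (z_x, z_y).

    Both weight vectors are z-scored across voxels first.  The angle
    theta = atan2(z_y, z_x) selects a 45-degree sector; sector boundaries
    belong to the counterclockwise neighbour.  Voxels with exactly zero
    z in both maps are excluded and counted.  ssd_k sums z_x^2 + z_y^2
    over the voxels of octant k.
    """
    x = np.asarray(w_x, dtype=float)
    y = np.asarray(w_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("weight vectors must be equal-length 1-D arrays")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant weight vector: z-scores undefined")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    nonzero = ~((zx == 0) & (zy == 0))
    theta = np.degrees(np.arctan2(zy[nonzero], zx[nonzero]))
    sector = np.floor((theta - 67.5) / 45.0).astype(int) % 8
    octant = _OCTANT_LOOKUP[sector]
    counts = np.bincount(octant, minlength=9)[1:]
    r2 = zx[nonzero] ** 2 + zy[nonzero] ** 2
    ssd = np.zeros(8)
    np.add.at(ssd, octant - 1, r2)
    octant_full = np.zeros(x.size, dtype=int)
    octant_full[nonzero] = octant
    return OctantSummary(
        counts=counts,
        ssd=ssd,
        excluded_zero=int(np.sum(~nonzero)),
        octant_of=octant_full,
    )
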