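"""Volume geometry and the masked-vector convention.

Every statistic, weight map and condition image in this package lives as a
1-D vector over the in-analysis voxels of a :class:`VolumeGrid`.  The
linearization order is fixed package-wide: Fortran order, i.e. the x axis
varies fastest.  3-D lattices are only materialized at I/O boundaries and
for connected-component operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """3-D lattice geometry plus the binary analysis mask.

    Parameters
    ----------
    shape :
        Number of voxels along (x, y, z).
    voxel_size_mm :
        Edge lengths of one voxel in millimetres.
    mask :
        Boolean array of ``shape``; True marks in-analysis voxels.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three positive integers, got {shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size_mm must be three positive reals, got {vox}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "mask", mask)
        # flat indices of masked voxels, x-fastest order
        object.__setattr__(
            self, "_flat_idx", np.flatnonzero(mask.ravel(order="F"))
        )

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (the length of every masked vector)."""
        return int(self._flat_idx.size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def mask_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates of masked voxels."""
        return np.stack(
            np.unravel_index(self._flat_idx, self.shape, order="F"), axis=1
        )

    def to_masked(self, volume: np.ndarray) -> np.ndarray:
        """Extract the masked vector from a full 3-D lattice."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(f"volume shape {volume.shape} != grid shape {self.shape}")
        return volume.ravel(order="F")[self._flat_idx]

    def to_volume(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back onto the full 3-D lattice."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vector.shape} != mask count ({self.n_voxels},)"
            )
        flat = np.full(int(np.prod(self.shape)), fill, dtype=np.result_type(vector, float))
        flat[self._flat_idx] = vector
        return flat.reshape(self.shape, order="F")

    def check_vector(self, vector: np.ndarray) -> np.ndarray:
        vector = np.asarray(vector, dtype=float)
        if vector.ndim != 1 or vector.size != self.n_voxels:
            raise ValueError(
                f"expected masked vector of length {self.n_voxels}, got shape {vector.shape}"
            )
        return vector


def make_grid(
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    mask_fill: float = 1.0,
    seed: int | None = None,
) -> VolumeGrid:
    """Build a grid whose mask covers a seeded random fraction of the lattice.

    ``round(mask_fill * n_total)`` voxels are marked in-mask, drawn uniformly
    without replacement, reproducibly from ``seed``.  ``mask_fill=1`` gives a
    full mask regardless of seed.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be three positive integers, got {shape}")
    if not (0 < mask_fill <= 1):
        raise ValueError(f"mask_fill must lie in (0, 1], got {mask_fill}")
    n_total = int(np.prod(shape))
    n_in = int(round(mask_fill * n_total))
    if n_in < 1:
        raise ValueError("mask_fill too small: zero voxels would remain")
    flat = np.zeros(n_total, dtype=bool)
    if n_in == n_total:
        flat[:] = True
    else:
        rng = np.random.default_rng(seed)
        flat[rng.choice(n_total, size=n_in, replace=False)] = True
    return VolumeGrid(shape, voxel_size_mm, flat.reshape(shape, order="F"))
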