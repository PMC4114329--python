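"""Group analysis mask and feature vectorization.

The classifier's feature space is defined by a *group mask*: the set of
voxels present in at least a threshold fraction (default 95%) of the training
subjects' individual masks.  The group mask is always built from training
subjects only, so feature dimensionality p varies across resampling
replicates and no information about the test subjects leaks into training.

Vectorization maps each subject's ReHo map to a length-p feature row, with a
fixed deterministic voxel ordering (lexicographic by the (x, y, z) index
tuple, i.e. C-order flattening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubjectMask", "GroupMask", "group_mask", "vectorize", "unvectorize"]

# tolerance for the inclusive >= threshold comparison: 0.95 * 20 slightly
# exceeds 19.0 in binary floating point, which would wrongly drop 19/20
_THRESH_EPS = 1e-9


@dataclass
class SubjectMask:
    """A subject's binary brain (or gray-matter) mask on the common grid."""

    data: np.ndarray
    source: str = "whole_brain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask is not binary; values found: {vals[:10]}")
        if self.source not in ("whole_brain", "gray_matter"):
            raise ValueError(f"unknown mask source {self.source!r}")
        self.data = self.data.astype(np.uint8)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class GroupMask:
    """Voxels present in >= threshold of the contributing subjects' masks.

    ``voxel_index`` is an (p, 3) array of voxel coordinates in deterministic
    lexicographic (x, y, z) order; column j of the feature matrix corresponds
    to voxel_index[j].
    """

    data: np.ndarray
    threshold: float
    n_subjects_used: int
    voxel_index: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]


def group_mask(masks: list[SubjectMask], threshold: float = 0.95) -> GroupMask:
    """Build the group mask: voxel kept iff present in >= threshold of the masks.

    The comparison is inclusive: with 20 subjects and threshold 0.95, a voxel
    present in exactly 19 masks is kept.
    """
    if not masks:
        raise ValueError("need at least one subject mask")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    grid = masks[0].grid_shape
    for i, m in enumerate(masks):
        if m.grid_shape != grid:
            raise ValueError(f"mask {i} grid {m.grid_shape} != {grid}")
    counts = np.zeros(grid, dtype=np.int64)
    for m in masks:
        counts += m.data
    # inclusive comparison, but a voxel absent from every mask is never kept
    # (threshold 0 yields the union, not the full grid)
    keep = counts >= max(threshold * len(masks) - _THRESH_EPS, 1.0)
    voxel_index = np.argwhere(keep)  # argwhere yields lexicographic (x, y, z) order
    return GroupMask(
        data=keep.astype(np.uint8),
        threshold=threshold,
        n_subjects_used=len(masks),
        voxel_index=voxel_index,
    )


def vectorize(maps: list, gmask: GroupMask) -> np.ndarray:
    """Stack ReHo maps into an n x p feature matrix over the group-mask voxels.

    Row i holds subject i's ReHo values at the p group-mask voxels in
    ``gmask.voxel_index`` order.
    """
    sel = gmask.data.astype(bool)
    rows = []
    for i, rmap in enumerate(maps):
        data = np.asarray(rmap.data if hasattr(rmap, "grid_shape") else rmap)
        if data.shape != gmask.grid_shape:
            raise ValueError(f"map {i} grid {data.shape} != group-mask grid {gmask.grid_shape}")
        rows.append(data[sel])  # boolean indexing is C-order = voxel_index order
    return np.vstack(rows)


def unvectorize(vector: np.ndarray, gmask: GroupMask) -> np.ndarray:
    """Scatter a length-p feature vector back to a 3D grid (zeros elsewhere)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (gmask.n_voxels,):
        raise ValueError(f"expected length-{gmask.n_voxels} vector, got shape {vector.shape}")
    out = np.zeros(gmask.grid_shape)
    out[gmask.data.astype(bool)] = vector
    return out
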