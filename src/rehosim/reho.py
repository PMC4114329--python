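"""Regional homogeneity: Kendall's coefficient of concordance over 3x3x3 neighborhoods.

Regional homogeneity (ReHo) quantifies the local temporal synchrony of the
BOLD signal.  For every in-mask voxel, the time series of all in-mask voxels
inside its 3x3x3 cube (m series, m <= 27) are rank-transformed and their
agreement is summarized by Kendall's coefficient of concordance

    W = 12 S / (m^2 (n^3 - n)),     S = sum_j (R_j - Rbar)^2,

where n is the number of timepoints, R_j the rank sum of timepoint j across
the m series, and Rbar = m (n + 1) / 2.  W lies in [0, 1]; W = 1 iff all m
rankings are identical and tie-free.  With tie correction the denominator
becomes m^2 (n^3 - n) - m * sum_i T_i, with T_i = sum_groups (t^3 - t) the
standard tie term of series i.

Boundary policy: all in-mask voxels of the cube contribute (partial
neighborhoods allowed); voxels with fewer than 2 in-mask cube voxels get
value 0.  A strict full-cube-only policy is available via ``full_cube_only``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

__all__ = ["RankMatrix", "ReHoMap", "rank_transform", "kendall_w", "reho_map"]


@dataclass
class RankMatrix:
    """Per-row average ranks of an m x n series matrix, plus tie-group sizes per row."""

    ranks: np.ndarray
    tie_counts: list[np.ndarray]

    @property
    def m(self) -> int:
        return self.ranks.shape[0]

    @property
    def n(self) -> int:
        return self.ranks.shape[1]

    def tie_terms(self) -> np.ndarray:
        """T_i = sum over tie groups of (t^3 - t), per row."""
        return np.array([float(np.sum(t.astype(float) ** 3 - t)) for t in self.tie_counts])


@dataclass
class ReHoMap:
    """Per-subject 3D map of Kendall's W values."""

    data: np.ndarray
    neighborhood_size: int = 27

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D map, got shape {self.data.shape}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


def rank_transform(series_matrix: np.ndarray) -> RankMatrix:
    """Rank each row (average ranks on ties), recording tie-group sizes.

    Rows are the m "judges" (voxel time series), columns the n "items"
    (timepoints).
    """
    x = np.asarray(series_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need an m x n matrix with m, n >= 2, got shape {x.shape}")
    if not np.isfinite(x).all():
        bad = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(
            f"non-finite value in series matrix at (row, col) ({int(bad[0])}, {int(bad[1])})"
        )
    ranks = rankdata(x, axis=1)
    tie_counts = []
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_counts.append(counts[counts > 1])
    return RankMatrix(ranks=ranks, tie_counts=tie_counts)


def kendall_w(ranks: RankMatrix | np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance of m rankings of n items.

    With all rankings identical and tie-free, W is exactly 1; with column
    rank sums all equal (e.g. two exactly reversed rankings), W is 0.
    If the tie-corrected denominator vanishes (all series fully tied),
    W is defined as 0.
    """
    if isinstance(ranks, np.ndarray):
        ranks = rank_transform(ranks)
    m, n = ranks.m, ranks.n
    if n < 2:
        raise ValueError("need at least 2 items (timepoints)")
    col_sums = ranks.ranks.sum(axis=0)
    rbar = m * (n + 1) / 2.0
    s = float(np.sum((col_sums - rbar) ** 2))
    denom = m * m * (n**3 - n)
    if tie_correction:
        denom = denom - m * float(ranks.tie_terms().sum())
    if denom <= 0:
        return 0.0
    return 12.0 * s / denom


def reho_map(
    volume,
    mask,
    tie_correction: bool = False,
    full_cube_only: bool = False,
) -> ReHoMap:
    """Voxelwise Kendall's W over each voxel's 3x3x3 in-mask neighborhood.

    Vectorized over the grid: each voxel's series is rank-transformed once
    (ranks are a per-series property), then neighborhood rank sums are formed
    with a 3x3x3 box correlation, from which S and W follow directly.  The
    result agrees with looping ``kendall_w`` over cube extracts, which the
    test suite checks.

    Parameters
    ----------
    volume : Volume4D
        (Preprocessed) time series.
    mask : SubjectMask or binary ndarray
        Voxels to include; out-of-mask voxels get 0, as do in-mask voxels
        with fewer than 2 in-mask cube voxels (or fewer than 27 when
        ``full_cube_only``).
    """
    mdata = np.asarray(mask.data if hasattr(mask, "grid_shape") else mask)
    if mdata.shape != volume.grid_shape:
        raise ValueError(f"mask grid {mdata.shape} != volume grid {volume.grid_shape}")
    mbin = (mdata != 0).astype(float)
    n = volume.n_timepoints
    if not np.isfinite(volume.data).all():
        bad = np.argwhere(~np.isfinite(volume.data))
        raise ValueError(f"non-finite value at voxel {tuple(bad[0][:3])}")

    ranks = rankdata(volume.data, axis=3)
    ranks *= mbin[..., None]

    kernel3 = np.ones((3, 3, 3))
    m_count = ndimage.correlate(mbin, kernel3, mode="constant", cval=0.0)
    # column rank sums R_j per voxel: box sum of masked ranks, each timepoint
    col_sums = ndimage.correlate(
        ranks, kernel3[..., None], mode="constant", cval=0.0
    )
    rbar = m_count * (n + 1) / 2.0
    s = np.sum((col_sums - rbar[..., None]) ** 2, axis=3)

    denom = m_count**2 * (n**3 - n)
    if tie_correction:
        tie_terms = _tie_terms_grid(volume.data, mbin)
        denom = denom - m_count * ndimage.correlate(
            tie_terms * mbin, kernel3, mode="constant", cval=0.0
        )

    min_m = 27 if full_cube_only else 2
    valid = (mbin > 0) & (m_count >= min_m) & (denom > 0)
    w = np.zeros(volume.grid_shape)
    np.divide(12.0 * s, denom, out=w, where=valid)
    w[~valid] = 0.0
    # guard against eps-level overshoot from float accumulation
    np.clip(w, 0.0, 1.0, out=w)
    return ReHoMap(data=w)


def _tie_terms_grid(data: np.ndarray, mbin: np.ndarray) -> np.ndarray:
    """Per-voxel tie term T = sum (t^3 - t) over groups of equal values."""
    out = np.zeros(data.shape[:3])
    for idx in np.argwhere(mbin > 0):
        _, counts = np.unique(data[tuple(idx)], return_counts=True)
        counts = counts[counts > 1].astype(float)
        out[tuple(idx)] = float(np.sum(counts**3 - counts))
    return out
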