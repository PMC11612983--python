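"""Population-vector analysis of directional coding.

Each cell contributes a smoothed (6 cm Gaussian), peak-normalised rate
profile; stacking them gives an (n_bins x n_cells) population matrix whose
rows are the population vectors at each spatial bin.  Pearson-correlating
the bin vectors of two direction (or session) conditions yields an
(n_bins x n_bins) similarity matrix; the degree to which the two directional
codes share structure is summarised by the peak of the offset-averaged
diagonal bands of the cross-direction matrix.  Orthogonal (decorrelated)
directional codes give a low score, shared codes a score near 1.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .core_io import DataError
from .preprocess import BinGrid
from .ratemaps import smooth_profile

__all__ = [
    "population_matrix",
    "pv_correlation",
    "cross_direction_score",
    "CrossDirectionScore",
]


def population_matrix(profiles: Sequence, grid: BinGrid,
                      smooth_sigma_cm: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Stack smoothed, peak-normalised profiles into an (n_bins, n_cells) matrix.

    Cells silent in this direction contribute an all-zero column and are
    flagged in the returned boolean array (they are kept so the cell
    ordering stays aligned across directions/sessions).

    Raises
    ------
    DataError
        If fewer than two cells have a nonzero profile.
    """
    cols = []
    silent = np.zeros(len(profiles), dtype=bool)
    for i, prof in enumerate(profiles):
        sm = smooth_profile(prof, smooth_sigma_cm, grid)
        peak = sm.max()
        if peak <= 0:
            silent[i] = True
            cols.append(np.zeros(grid.n_bins))
        else:
            cols.append(sm / peak)
    if (~silent).sum() < 2:
        raise DataError("population matrix needs at least 2 active cells")
    return np.column_stack(cols), silent


def pv_correlation(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Pearson correlation between the bin vectors of two population matrices.

    Entry (i, j) correlates row i of ``mat_a`` with row j of ``mat_b``
    across cells; the cell lists must be identical and identically ordered.
    Rows with zero variance yield NaN entries.
    """
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    if A.shape != B.shape:
        raise DataError("population matrices must have identical shapes")
    if A.shape[1] < 2:
        raise DataError("Pearson correlation needs at least 2 cells")
    az = A - A.mean(axis=1, keepdims=True)
    bz = B - B.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (az @ bz.T) / np.outer(asd, bsd)
    corr[asd == 0, :] = np.nan
    corr[:, bsd == 0] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


class CrossDirectionScore(NamedTuple):
    score: float
    offset: int


def cross_direction_score(corr: np.ndarray, min_band: int = 5,
                          method: str = "band") -> CrossDirectionScore:
    """Peak of the offset-averaged diagonal bands of a cross-direction matrix.

    For every positional offset ``d`` the mean of the entries on the
    diagonal at that offset is taken (missing entries excluded pairwise);
    the score is the maximum over offsets and the argmax offset is returned
    with it.  Bands shorter than ``min_band`` entries are ignored so a
    single corner coefficient cannot dominate.  ``method="rowmax"`` instead
    averages each row's maximum (a sensitivity alternative).
    """
    M = np.asarray(corr, dtype=float)
    if M.ndim != 2:
        raise DataError("correlation matrix must be 2-D")
    if np.all(np.isnan(M)):
        raise DataError("correlation matrix is entirely missing")
    if method == "rowmax":
        with np.errstate(all="ignore"):
            row_max = np.nanmax(M, axis=1)
        return CrossDirectionScore(float(np.nanmean(row_max)), 0)
    if method != "band":
        raise ValueError(f"unknown method {method!r}")
    n_rows, n_cols = M.shape
    best = -np.inf
    best_offset = 0
    for d in range(-(n_rows - min_band), n_cols - min_band + 1):
        band = np.diagonal(M, offset=d)
        if band.size < min_band or np.all(np.isnan(band)):
            continue
        m = np.nanmean(band)
        if m > best:
            best = m
            best_offset = d
    if not np.isfinite(best):
        raise DataError("no diagonal band with enough valid entries")
    return CrossDirectionScore(float(best), int(best_offset))
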