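"""Poisson assignment of histone marks to called nucleosomes.

For every (nucleosome call, mark) pair the observed count ``k`` is the
number of the mark's reads whose inferred fragment centre (midpoint of
the 150-nt extension) falls inside the peak. The expectation under
chromosome-wide uniformity is the length-proportional share

    lambda = (mark's reads on the chromosome) * peak_width / chrom_length,

and the upper-tail probability ``P(X >= k)`` of ``Poisson(lambda)`` is
compared against the assignment threshold ``p < 1e-3`` (strict). The
result over all pairs is the binary assignment matrix, the central
object of the nucleosome-level histone-code analysis.

Counting by fragment centre (rather than any-overlap of the 75-nt
segment) keeps the test calibrated: a uniformly placed read lands its
centre in a width-w window with probability w / L, exactly matching the
lambda formula, so the false-assignment rate on background stays below
the nominal threshold.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ShapeError, UnknownChromosomeError
from .reads import central_segments

ASSIGNMENT_THRESHOLD = 1e-3


def poisson_upper_tail(k, lam):
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Poisson(lam)``.

    ``k = 0`` gives 1 (the whole distribution); ``lam = 0`` with ``k > 0``
    gives 0. Accepts scalars or arrays; rejects negative inputs.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be a non-negative integer")
    if not np.issubdtype(k_arr.dtype, np.integer) and np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be integral")
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be non-negative")
    p = stats.poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(p)
    return p


def expected_rate(total_reads: int, chrom_length: int, peak_width: int) -> float:
    """Expected reads in a peak under uniformity: the mark's
    chromosome-wide total scaled by ``peak_width / chrom_length``."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    return total_reads * peak_width / chrom_length


def assign_marks(
    calls: pd.DataFrame,
    reads: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    threshold: float = ASSIGNMENT_THRESHOLD,
    marks: list[str] | None = None,
    ext: int = 150,
    core: int = 75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (call, mark) pair and build the binary matrix.

    Parameters
    ----------
    calls
        Nucleosome calls with ``chrom``, ``start``, ``end`` columns
        (any interval set works, e.g. a tiling of candidate windows).
    reads
        BED6 reads, ``name`` = mark id.
    threshold
        Assignment iff ``p < threshold`` (strict), default 1e-3.
    marks
        Column order of the matrix; defaults to sorted mark ids seen in
        ``reads``.

    Returns
    -------
    tests, matrix
        ``tests``: long table (nucleosome, mark, k, expected, p, assigned);
        ``matrix``: calls x marks {0,1} DataFrame, rows labelled
        ``chrom:start-end``.
    """
    if marks is None:
        marks = sorted(reads["name"].unique())
    unknown = set(calls["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise UnknownChromosomeError(
            f"calls on chromosomes missing from sizes table: {sorted(unknown)}")

    n_calls, n_marks = len(calls), len(marks)
    row_ids = [f"{c}:{s}-{e}" for c, s, e in
               zip(calls["chrom"], calls["start"], calls["end"])]
    k_mat = np.zeros((n_calls, n_marks), dtype=np.int64)
    lam_mat = np.zeros((n_calls, n_marks), dtype=float)

    segments = central_segments(reads, chrom_lengths, ext=ext, core=core)
    mark_index = {m: j for j, m in enumerate(marks)}
    # sorted fragment-centre arrays and totals per (chrom, mark)
    centres: dict[tuple[str, str], np.ndarray] = {}
    totals = np.zeros((len(chrom_lengths), n_marks), dtype=np.int64)
    chrom_order = {c: i for i, c in enumerate(chrom_lengths)}
    for (chrom, mark), sub in segments.groupby(["chrom", "mark"], sort=False):
        if mark not in mark_index:
            continue
        centres[(chrom, mark)] = np.sort(sub["center"].to_numpy(dtype=np.int64))
        totals[chrom_order[chrom], mark_index[mark]] = len(sub)

    call_chrom = calls["chrom"].to_numpy()
    call_start = calls["start"].to_numpy(dtype=np.int64)
    call_end = calls["end"].to_numpy(dtype=np.int64)
    for chrom, length in chrom_lengths.items():
        sel = np.flatnonzero(call_chrom == chrom)
        if sel.size == 0:
            continue
        widths = call_end[sel] - call_start[sel]
        for mark, j in mark_index.items():
            pos = centres.get((chrom, mark))
            if pos is not None and pos.size:
                k_mat[sel, j] = (np.searchsorted(pos, call_end[sel], side="left")
                                 - np.searchsorted(pos, call_start[sel], side="left"))
            lam_mat[sel, j] = totals[chrom_order[chrom], j] * widths / int(length)

    p_mat = stats.poisson.sf(k_mat - 1, lam_mat)
    assigned = p_mat < threshold
    matrix = pd.DataFrame(assigned.astype(np.int8), index=row_ids, columns=marks)

    tests = pd.DataFrame({
        "nucleosome": np.repeat(row_ids, n_marks) if n_calls else [],
        "mark": np.tile(marks, n_calls) if n_calls else [],
        "k": k_mat.ravel(),
        "expected": lam_mat.ravel(),
        "p": p_mat.ravel(),
        "assigned": assigned.ravel(),
    })
    return tests, matrix


def matrix_dimensions_ok(matrix: pd.DataFrame, n_calls: int, n_marks: int) -> bool:
    """Shape contract helper: (#calls, M) with binary entries."""
    if matrix.shape != (n_calls, n_marks):
        raise ShapeError(f"matrix shape {matrix.shape} != ({n_calls}, {n_marks})")
    return bool(matrix.isin([0, 1]).all().all())
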