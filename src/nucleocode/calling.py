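"""Nucleosome calling on pooled central-segment coverage.

Candidate peaks are maximal runs of coverage at or above ``min_height``
(runs separated by fewer than ``min_gap`` sub-threshold bases are
merged) — a simple, documented stand-in for the NPS edge detector, scored
against planted truth. Two published post-detection filters are then
applied: peaks whose reads are significantly uneven between strands
(exact two-sided binomial test against 0.5) are removed, as are peaks
narrower than 80 nt or wider than 250 nt (inclusive bounds kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .reads import CoverageProfile, central_segments

#: Columns of a candidate-peak table.
CANDIDATE_COLUMNS = ["chrom", "start", "end", "summit", "height",
                     "forward_reads", "reverse_reads"]


@dataclass(frozen=True)
class CallParams:
    """Tunable parameters of the caller.

    ``min_height``/``min_gap`` drive candidate detection;
    ``strand_alpha`` is the significance level of the strand-evenness
    filter; width bounds are inclusive; ``ext``/``core`` set the read
    model (150/75 nt).
    """
    min_height: int = 5
    min_gap: int = 30
    strand_alpha: float = 0.05
    min_width: int = 80
    max_width: int = 250
    ext: int = 150
    core: int = 75


def detect_candidates(cov: CoverageProfile | np.ndarray, min_height: int,
                      min_gap: int, chrom: str | None = None) -> pd.DataFrame:
    """Find maximal runs of coverage >= ``min_height``; merge runs whose
    separating sub-threshold gap is shorter than ``min_gap`` bases.
    Summit is the leftmost maximum of the (merged) run."""
    if min_height < 1:
        raise ValueError("min_height must be >= 1")
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if isinstance(cov, CoverageProfile):
        values, chrom = cov.values, cov.chrom
    else:
        values = np.asarray(cov)
    mask = values >= min_height
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate(([0], starts))
    if mask.size and mask[-1]:
        ends = np.concatenate((ends, [mask.size]))

    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))

    rows = []
    for s, e in merged:
        run = values[s:e]
        summit = s + int(np.argmax(run))
        rows.append((chrom, s, e, summit, int(values[summit]), 0, 0))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def strand_evenness_p(forward: np.ndarray, reverse: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p-value for forward successes out of
    forward+reverse trials at probability 1/2 (vectorised).

    ``p = min(1, 2 * P(X <= min(f, r)))`` by symmetry of Binomial(n, 1/2);
    zero total reads gives p = 1 (vacuous evidence).
    """
    forward = np.asarray(forward, dtype=np.int64)
    reverse = np.asarray(reverse, dtype=np.int64)
    n = forward + reverse
    m = np.minimum(forward, reverse)
    with np.errstate(divide="ignore"):
        p = 2.0 * stats.binom.cdf(m, np.maximum(n, 1), 0.5)
    p = np.where(n == 0, 1.0, np.minimum(p, 1.0))
    return p


def strand_evenness_test(forward: int, reverse: int,
                         alpha: float = 0.05) -> tuple[float, bool]:
    """Strand filter for one peak: keep iff the exact two-sided binomial
    p-value is >= ``alpha``."""
    p = float(strand_evenness_p(np.array([forward]), np.array([reverse]))[0])
    return p, p >= alpha


def width_filter(width: int, min_width: int = 80, max_width: int = 250) -> bool:
    """Keep iff ``min_width <= width <= max_width`` (removal is strict:
    only widths below 80 or above 250 are dropped)."""
    return min_width <= width <= max_width


def apply_filters(candidates: pd.DataFrame,
                  params: CallParams = CallParams()) -> pd.DataFrame:
    """Annotate candidates with both filter outcomes and return them with
    ``width``, ``p_strand``, ``strand_pass`` and ``width_pass`` columns."""
    out = candidates.copy()
    out["width"] = out["end"] - out["start"]
    out["p_strand"] = strand_evenness_p(out["forward_reads"].to_numpy(),
                                        out["reverse_reads"].to_numpy())
    out["strand_pass"] = out["p_strand"] >= params.strand_alpha
    out["width_pass"] = ((out["width"] >= params.min_width)
                         & (out["width"] <= params.max_width))
    return out


def count_strand_reads(candidates: pd.DataFrame,
                       segments: pd.DataFrame) -> pd.DataFrame:
    """Attach per-strand counts of reads whose central segment overlaps each
    candidate by >= 1 bp."""
    out = candidates.copy()
    fwd = np.zeros(len(out), dtype=np.int64)
    rev = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in segments.groupby("chrom", sort=False):
        sel = np.flatnonzero((out["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        p_start = out["start"].to_numpy()[sel]
        p_end = out["end"].to_numpy()[sel]
        for is_rev, acc in ((False, fwd), (True, rev)):
            ss = sub[(sub["strand"] == "-") == is_rev]
            starts = np.sort(ss["start"].to_numpy(dtype=np.int64))
            ends = np.sort(ss["end"].to_numpy(dtype=np.int64))
            # overlap <=> seg.start < peak.end and seg.end > peak.start
            acc[sel] = (np.searchsorted(starts, p_end, side="left")
                        - np.searchsorted(ends, p_start, side="right"))
    out["forward_reads"] = fwd
    out["reverse_reads"] = rev
    return out


def call_nucleosomes(reads: pd.DataFrame, chrom_lengths: Mapping[str, int],
                     params: CallParams = CallParams(),
                     return_candidates: bool = False):
    """Full caller: central segments -> pooled coverage -> candidate runs
    -> strand counts -> strand + width filters.

    Returns the sorted, non-overlapping calls table (BED-like columns plus
    ``summit``, ``height``, ``width``, ``forward_reads``, ``reverse_reads``,
    ``p_strand``); with ``return_candidates=True`` also the annotated
    candidate table including filter flags.
    """
    from .reads import build_coverage

    segments = central_segments(reads, chrom_lengths, ext=params.ext,
                                core=params.core)
    coverage = build_coverage(segments, chrom_lengths)
    cand_parts = [
        detect_candidates(coverage[chrom], params.min_height, params.min_gap)
        for chrom in chrom_lengths
    ]
    candidates = pd.concat(cand_parts, ignore_index=True) if cand_parts else \
        pd.DataFrame(columns=CANDIDATE_COLUMNS)
    candidates = count_strand_reads(candidates, segments)
    annotated = apply_filters(candidates, params)
    calls = annotated[annotated["strand_pass"] & annotated["width_pass"]]
    calls = calls.drop(columns=["strand_pass", "width_pass"])
    calls = calls.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if return_candidates:
        return calls, annotated
    return calls
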