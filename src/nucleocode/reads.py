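"""Read model: fragment extension, central segments and pooled coverage.

Each 36-nt mapped read is extended to 150 nt from its 5' end (forward
reads extend rightwards, reverse reads leftwards) to approximate the
nucleosome-protected fragment, and the central 75 nt of the extension are
kept as the positioning signal. Pooled per-base coverage of these central
segments over all marks is the track nucleosome peaks are detected on.

Coordinates are 0-based half-open throughout; fragments are clipped to
chromosome bounds and clipped fragments shorter than the core are kept
whole, so coverage mass is preserved away from edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import UnknownChromosomeError

EXTENSION_BP = 150
CORE_BP = 75


class MappedRead(NamedTuple):
    """One aligned ChIP-seq read (0-based half-open)."""
    chrom: str
    start: int
    end: int
    strand: str
    mark: str


class Fragment(NamedTuple):
    """An extended fragment or its central segment."""
    chrom: str
    start: int
    end: int
    strand: str
    mark: str


@dataclass
class CoverageProfile:
    """Per-base pooled central-segment coverage for one chromosome."""
    chrom: str
    values: np.ndarray

    @property
    def total(self) -> int:
        return int(self.values.sum())


def extend_read(read: MappedRead, chrom_length: int,
                ext: int = EXTENSION_BP) -> Fragment:
    """Extend a read to ``ext`` nt from its 5' end, clipped to the chromosome.

    Forward reads give ``[start, start+ext)``; reverse reads
    ``[end-ext, end)``.
    """
    if read.strand == "-":
        start, end = read.end - ext, read.end
    else:
        start, end = read.start, read.start + ext
    return Fragment(read.chrom, max(0, start), min(int(chrom_length), end),
                    read.strand, read.mark)


def central_segment(frag: Fragment, core: int = CORE_BP) -> Fragment:
    """Take the central ``core`` nt of a fragment (floor-centred offset;
    a 150-nt fragment yields offset 37). Fragments shorter than the core
    (edge-clipped) are returned whole."""
    length = frag.end - frag.start
    if length <= core:
        return frag
    off = (length - core) // 2
    return Fragment(frag.chrom, frag.start + off, frag.start + off + core,
                    frag.strand, frag.mark)


def central_segments(reads: pd.DataFrame, chrom_lengths: Mapping[str, int],
                     ext: int = EXTENSION_BP, core: int = CORE_BP) -> pd.DataFrame:
    """Vectorised ``extend_read`` + ``central_segment`` over a BED6 frame.

    Returns a DataFrame ``(chrom, start, end, strand, mark, center)`` where
    ``center`` is the floor midpoint of the segment — the fragment-centre
    estimate used when counting reads toward peaks.
    """
    unknown = set(reads["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise UnknownChromosomeError(
            f"reads on chromosomes missing from sizes table: {sorted(unknown)}")
    lengths = reads["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
    r_start = reads["start"].to_numpy(dtype=np.int64)
    r_end = reads["end"].to_numpy(dtype=np.int64)
    rev = (reads["strand"] == "-").to_numpy()

    f_start = np.where(rev, r_end - ext, r_start)
    f_end = np.where(rev, r_end, r_start + ext)
    f_start = np.maximum(f_start, 0)
    f_end = np.minimum(f_end, lengths)

    length = f_end - f_start
    off = np.where(length > core, (length - core) // 2, 0)
    s_start = f_start + off
    s_end = np.where(length > core, s_start + core, f_end)
    return pd.DataFrame({
        "chrom": reads["chrom"].to_numpy(),
        "start": s_start,
        "end": s_end,
        "strand": reads["strand"].to_numpy(),
        "mark": reads["name"].to_numpy(),
        "center": (s_start + s_end) // 2,
    })


def build_coverage(segments: pd.DataFrame,
                   chrom_lengths: Mapping[str, int]) -> dict[str, CoverageProfile]:
    """Pool central segments (all marks) into per-base coverage per chromosome.

    ``coverage[b]`` = number of segments containing base ``b``.
    """
    unknown = set(segments["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise UnknownChromosomeError(
            f"segments on chromosomes missing from sizes table: {sorted(unknown)}")
    out: dict[str, CoverageProfile] = {}
    grouped = dict(iter(segments.groupby("chrom", sort=False)))
    for chrom, length in chrom_lengths.items():
        length = int(length)
        diff = np.zeros(length + 1, dtype=np.int64)
        if chrom in grouped:
            sub = grouped[chrom]
            np.add.at(diff, sub["start"].to_numpy(dtype=np.int64), 1)
            np.add.at(diff, sub["end"].to_numpy(dtype=np.int64), -1)
        values = np.cumsum(diff[:-1]).astype(np.int32)
        out[chrom] = CoverageProfile(chrom=chrom, values=values)
    return out
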