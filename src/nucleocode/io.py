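"""Plain-text genomics I/O: BED6, bedGraph, chromosome sizes and TSV matrices.

All interval formats are 0-based half-open, matching BED. Reads and
nucleosome calls travel as pandas DataFrames with documented columns;
matrices are DataFrames with labelled rows/columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Column schema for a mapped-read / generic interval table (BED6).
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<length>`` table into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{int(length)}\n")


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame with :data:`BED6_COLUMNS`."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLUMNS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "score": np.int64, "strand": str},
    )
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write interval records as BED6 (tab-separated, no header)."""
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(values_by_chrom: Mapping[str, np.ndarray], path) -> None:
    """Write per-base vectors as a run-length-encoded bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for chrom, values in values_by_chrom.items():
            v = np.asarray(values)
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]}\n")


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a labelled matrix (e.g. the binary assignment matrix) as TSV."""
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
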