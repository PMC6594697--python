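"""Synthetic ChIP-seq with a planted histone code.

The generator emulates a multi-mark ChIP-seq collection over a genome of
regularly spaced nucleosomes. Each nucleosome carries one of K chromatin
*states* drawn as a run-length process (runs of mean length
``domain_length / spacing`` nucleosomes, giving tunable higher-order
domain structure). Each of M histone marks belongs to one planted cluster;
a mark *fires* on a nucleosome with probability ``p_in`` when the
nucleosome's state matches the mark's cluster and ``p_out`` otherwise.
Every firing (nucleosome, mark) pair sheds ``Poisson(signal_depth)``
sequencing reads: a 147-bp core-particle fragment is centred on the dyad
plus Gaussian positional jitter, the read is taken from the fragment's
5' end on a fair-coin strand, and uniform background reads are added per
mark at ``background_rate`` per kb. The planted dyads, states, firing
matrix and mark clusters are returned as ground truth so every
downstream stage (calling, assignment, clustering, multi-scale
persistence) can be scored.

A single seeded NumPy generator drives the whole simulation, so identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import BED6_COLUMNS

#: Length of the nucleosome-protected fragment used for read placement.
CORE_PARTICLE_BP = 147


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ChIP-seq collection.

    Parameters
    ----------
    chrom_lengths
        Ordered map chromosome name -> length in bp. Lengths must exceed
        ``spacing``.
    cluster_partition
        Map mark-id -> cluster label in ``1..K``; every label in the range
        must own at least one mark (surjective).
    spacing
        Nucleosome repeat length in bp; dyads sit at ``spacing/2``,
        ``3*spacing/2``, ... on each chromosome.
    p_in, p_out
        Firing probabilities for state-matched / unmatched (mark,
        nucleosome) pairs.
    signal_depth
        Mean reads per firing (mark, nucleosome) pair.
    background_rate
        Mean background reads per mark per kb of genome.
    jitter_sd
        Standard deviation (bp) of the fragment-centre displacement
        around the planted dyad, drawn per read.
    read_length
        Sequenced read length in bp (36 by default, short-read era).
    domain_length
        Mean length (bp) of contiguous same-state nucleosome runs;
        ``domain_length == spacing`` degenerates to independent states
        per nucleosome (no higher-order structure).
    seed
        Seed of the single RNG stream driving the simulation.
    """

    chrom_lengths: Mapping[str, int]
    cluster_partition: Mapping[str, int]
    spacing: int = 200
    p_in: float = 0.8
    p_out: float = 0.05
    signal_depth: float = 20.0
    background_rate: float = 0.1
    jitter_sd: float = 15.0
    read_length: int = 36
    domain_length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def marks(self) -> list[str]:
        """Mark ids in declaration order."""
        return list(self.cluster_partition)

    @property
    def n_marks(self) -> int:
        return len(self.cluster_partition)

    @property
    def n_clusters(self) -> int:
        return max(self.cluster_partition.values())

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must name at least one chromosome")
        if not self.cluster_partition:
            raise ConfigError("cluster_partition must name at least one mark")
        for p, name in [(self.p_in, "p_in"), (self.p_out, "p_out")]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.spacing < self.read_length:
            raise ConfigError("spacing must be >= read_length")
        if self.domain_length < self.spacing:
            raise ConfigError("domain_length must be >= spacing")
        if self.signal_depth < 0 or self.background_rate < 0 or self.jitter_sd < 0:
            raise ConfigError("rates and jitter_sd must be non-negative")
        labels = set(self.cluster_partition.values())
        k = max(labels)
        if labels != set(range(1, k + 1)):
            raise ConfigError(
                f"cluster labels must cover 1..K with no gaps, got {sorted(labels)}")
        for chrom, length in self.chrom_lengths.items():
            if length <= self.spacing:
                raise ConfigError(f"chromosome {chrom!r} shorter than spacing")


def default_config(
    n_marks: int = 12,
    n_clusters: int = 4,
    chrom_lengths: Mapping[str, int] | None = None,
    **overrides,
) -> SimConfig:
    """Default study conditions: one 500-kb chromosome, 12 marks in 4
    balanced clusters, 200-bp repeat, p_in=0.8 / p_out=0.05, depth 20,
    background 0.1 reads/kb/mark, 15-bp jitter, 36-nt reads, 10-kb domains.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 500_000}
    width = len(str(n_marks))
    partition = {
        f"M{i + 1:0{width}d}": (i * n_clusters) // n_marks + 1
        for i in range(n_marks)
    }
    return SimConfig(chrom_lengths=dict(chrom_lengths),
                     cluster_partition=partition, **overrides)


@dataclass
class GroundTruth:
    """Planted truth for one simulation.

    Attributes
    ----------
    dyads
        DataFrame ``(chrom, pos)`` of planted dyad positions, in
        simulation order (chromosomes in config order, positions ascending).
    states
        Per-nucleosome chromatin state label in ``1..K`` (aligned to dyads).
    membership
        uint8 matrix nucleosomes x marks; 1 where the mark fires.
    marks
        Mark ids (column order of ``membership``).
    mark_clusters
        Planted map mark-id -> cluster label.
    """

    dyads: pd.DataFrame
    states: np.ndarray
    membership: np.ndarray
    marks: list[str]
    mark_clusters: dict[str, int] = field(default_factory=dict)

    @property
    def n_nucleosomes(self) -> int:
        return len(self.states)

    def __eq__(self, other) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.dyads.reset_index(drop=True).equals(other.dyads.reset_index(drop=True))
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.membership, other.membership)
            and self.marks == other.marks
            and self.mark_clusters == other.mark_clusters
        )


def _simulate_states(n: int, k: int, p_resample: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Run-length state process: at each nucleosome, with probability
    ``p_resample`` the state is redrawn uniformly over all K labels."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    candidates = rng.integers(1, k + 1, size=n)
    fresh = rng.random(n) < p_resample
    fresh[0] = True
    idx = np.cumsum(fresh) - 1
    return candidates[np.flatnonzero(fresh)][idx]


def simulate_genome_truth(config: SimConfig) -> GroundTruth:
    """Plant dyads, states and the firing matrix for ``config``.

    Dyads are placed at ``spacing/2 + i*spacing``; states follow the
    run-length process (mean run ``domain_length/spacing`` nucleosomes,
    exactly independent states when ``domain_length == spacing``);
    ``membership[i, m] ~ Bernoulli(p_in)`` when ``cluster(m) == state(i)``
    and ``Bernoulli(p_out)`` otherwise. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters
    # Resample probability chosen so mean run length is domain_length/spacing
    # when uncapped; cap 1 gives iid states in the domain-free limit.
    if k > 1:
        p_resample = min(1.0, (config.spacing / config.domain_length) * k / (k - 1))
    else:
        p_resample = 1.0

    chroms, positions, state_parts = [], [], []
    for chrom, length in config.chrom_lengths.items():
        n = int(length) // config.spacing
        pos = config.spacing // 2 + config.spacing * np.arange(n, dtype=np.int64)
        chroms.extend([chrom] * n)
        positions.append(pos)
        state_parts.append(_simulate_states(n, k, p_resample, rng))
    dyads = pd.DataFrame({
        "chrom": pd.Series(chroms, dtype=object),
        "pos": np.concatenate(positions) if positions else np.zeros(0, np.int64),
    })
    states = np.concatenate(state_parts) if state_parts else np.zeros(0, np.int64)

    cluster_of_mark = np.array([config.cluster_partition[m] for m in config.marks])
    match = states[:, None] == cluster_of_mark[None, :]
    p = np.where(match, config.p_in, config.p_out)
    membership = (rng.random(p.shape) < p).astype(np.uint8)
    return GroundTruth(dyads=dyads, states=states, membership=membership,
                       marks=config.marks,
                       mark_clusters=dict(config.cluster_partition))


def simulate_reads(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Draw mapped reads for the planted truth.

    For each firing (nucleosome, mark) pair, ``Poisson(signal_depth)``
    reads are generated from a 147-bp fragment centred at
    ``dyad + Normal(0, jitter_sd)`` (jitter per read). Strand is a fair
    coin; the read covers the fragment's 5' end on its strand (forward:
    fragment start; reverse: fragment end minus read length, reported on
    '-'). Background reads are uniform per mark at ``background_rate``
    per kb. Reads are shifted, if needed, to lie within the chromosome,
    and the result is sorted by (chrom, start, end, strand, mark).

    Returns a BED6-style DataFrame (columns :data:`~nucleocode.io.BED6_COLUMNS`,
    ``name`` = mark id, ``score`` = 0).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    read_len = config.read_length
    half = (CORE_PARTICLE_BP - 1) / 2.0  # fragment start = centre - 73

    marks = np.array(truth.marks)
    chrom_of_row = truth.dyads["chrom"].to_numpy()
    pos_of_row = truth.dyads["pos"].to_numpy()

    parts: list[pd.DataFrame] = []
    for chrom, length in config.chrom_lengths.items():
        length = int(length)
        rows = np.flatnonzero(chrom_of_row == chrom)
        sub = truth.membership[rows]
        nz_i, nz_m = np.nonzero(sub)
        counts = rng.poisson(config.signal_depth, size=nz_i.size)
        rep_i = np.repeat(rows[nz_i], counts)
        rep_m = np.repeat(nz_m, counts)
        total = rep_i.size
        centres = pos_of_row[rep_i] + rng.normal(0.0, config.jitter_sd, size=total)
        frag_start = np.rint(centres - half).astype(np.int64)
        frag_end = frag_start + CORE_PARTICLE_BP
        forward = rng.random(total) < 0.5
        start = np.where(forward, frag_start, frag_end - read_len)
        sig = pd.DataFrame({
            "chrom": chrom,
            "start": start,
            "strand": np.where(forward, "+", "-"),
            "name": marks[rep_m],
        })

        bg_parts = []
        for m in truth.marks:
            n_bg = rng.poisson(config.background_rate * length / 1000.0)
            if n_bg == 0:
                continue
            b_start = rng.integers(0, length - read_len + 1, size=n_bg)
            b_fwd = rng.random(n_bg) < 0.5
            bg_parts.append(pd.DataFrame({
                "chrom": chrom,
                "start": b_start.astype(np.int64),
                "strand": np.where(b_fwd, "+", "-"),
                "name": m,
            }))
        part = pd.concat([sig, *bg_parts], ignore_index=True)
        part["start"] = part["start"].clip(0, length - read_len)
        parts.append(part)

    if parts:
        reads = pd.concat(parts, ignore_index=True)
    else:  # pragma: no cover - config always has >=1 chromosome
        reads = pd.DataFrame(columns=["chrom", "start", "strand", "name"])
    reads["end"] = reads["start"] + read_len
    reads["score"] = 0
    reads = reads.sort_values(
        ["chrom", "start", "end", "strand", "name"], kind="mergesort"
    ).reset_index(drop=True)
    return reads.loc[:, BED6_COLUMNS]


# ---------------------------------------------------------------------------
# Truth round-trip


def write_truth(truth: GroundTruth, directory) -> None:
    """Write ground truth as plain text: ``dyads.bed`` (single-base BED6,
    name = state label), ``membership.tsv`` and ``mark_clusters.tsv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bed = pd.DataFrame({
        "chrom": truth.dyads["chrom"],
        "start": truth.dyads["pos"],
        "end": truth.dyads["pos"] + 1,
        "name": truth.states,
        "score": 0,
        "strand": ".",
    })
    bed.to_csv(d / "dyads.bed", sep="\t", header=False, index=False)
    row_ids = [f"{c}:{p}" for c, p in zip(truth.dyads["chrom"], truth.dyads["pos"])]
    pd.DataFrame(truth.membership, index=row_ids, columns=truth.marks).to_csv(
        d / "membership.tsv", sep="\t")
    pd.DataFrame({"mark": list(truth.mark_clusters),
                  "cluster": list(truth.mark_clusters.values())}).to_csv(
        d / "mark_clusters.tsv", sep="\t", index=False)


def read_truth(directory) -> GroundTruth:
    """Inverse of :func:`write_truth`."""
    d = Path(directory)
    try:
        bed = pd.read_csv(d / "dyads.bed", sep="\t", header=None,
                          names=BED6_COLUMNS,
                          dtype={"chrom": str, "start": np.int64,
                                 "end": np.int64, "name": np.int64})
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=BED6_COLUMNS).astype(
            {"start": np.int64, "end": np.int64})
    membership = pd.read_csv(d / "membership.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(d / "mark_clusters.tsv", sep="\t",
                           dtype={"mark": str, "cluster": np.int64})
    marks = [str(m) for m in membership.columns]
    return GroundTruth(
        dyads=pd.DataFrame({"chrom": bed["chrom"].astype(str),
                            "pos": bed["start"].astype(np.int64)}),
        states=bed["name"].to_numpy(dtype=np.int64),
        membership=membership.to_numpy(dtype=np.uint8),
        marks=marks,
        mark_clusters=dict(zip(clusters["mark"], clusters["cluster"].astype(int))),
    )
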