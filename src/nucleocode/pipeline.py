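"""End-to-end pipeline and truth-scoring helpers.

``run_histone_code`` chains the full nucleosome-level analysis —
simulate, call nucleosomes, assign marks, correlate, cluster — and the
scoring helpers compare each stage against the planted ground truth:
dyad recovery (recall/precision at a positional tolerance), assignment
accuracy (balanced accuracy of matrix entries on matched calls) and
cluster recovery (adjusted Rand index of mark partitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .assignment import assign_marks
from .calling import CallParams, call_nucleosomes
from .clustering import ClusterResult, MarkCorrelationMatrix, cluster_marks, \
    phi_correlation
from .simulate import GroundTruth, SimConfig, simulate_genome_truth, simulate_reads

MATCH_TOLERANCE_BP = 40


@dataclass
class HistoneCodeResult:
    """Everything the nucleosome-level analysis produces for one dataset."""
    config: SimConfig
    truth: GroundTruth
    reads: pd.DataFrame
    calls: pd.DataFrame
    tests: pd.DataFrame
    matrix: pd.DataFrame
    correlation: MarkCorrelationMatrix
    clusters: ClusterResult


def run_histone_code(config: SimConfig, params: CallParams = CallParams(),
                     k: int | None = None,
                     threshold: float = 1e-3) -> HistoneCodeResult:
    """Simulate a dataset and run calling, assignment and clustering."""
    truth = simulate_genome_truth(config)
    reads = simulate_reads(config, truth)
    calls = call_nucleosomes(reads, config.chrom_lengths, params)
    tests, matrix = assign_marks(calls, reads, config.chrom_lengths,
                                 threshold=threshold, marks=config.marks,
                                 ext=params.ext, core=params.core)
    corr = phi_correlation(matrix)
    clusters = cluster_marks(corr, k if k is not None else config.n_clusters)
    return HistoneCodeResult(config=config, truth=truth, reads=reads,
                             calls=calls, tests=tests, matrix=matrix,
                             correlation=corr, clusters=clusters)


def match_calls(calls: pd.DataFrame, truth: GroundTruth,
                tolerance: int = MATCH_TOLERANCE_BP) -> tuple[float, float, np.ndarray]:
    """Score calls against planted dyads.

    A dyad is *recovered* when some call midpoint lies within
    ``tolerance`` bp; a call is *correct* when its midpoint lies within
    ``tolerance`` of some dyad. Returns ``(recall, precision, dyad_of_call)``
    where ``dyad_of_call[i]`` is the row of the nearest matched dyad or -1.
    """
    n_dyads = truth.n_nucleosomes
    dyad_of_call = np.full(len(calls), -1, dtype=np.int64)
    recovered = np.zeros(n_dyads, dtype=bool)
    truth_chrom = truth.dyads["chrom"].to_numpy()
    truth_pos = truth.dyads["pos"].to_numpy()
    mid = ((calls["start"].to_numpy() + calls["end"].to_numpy()) // 2
           if len(calls) else np.zeros(0, np.int64))
    call_chrom = calls["chrom"].to_numpy() if len(calls) else np.zeros(0, object)
    for chrom in pd.unique(truth_chrom):
        t_rows = np.flatnonzero(truth_chrom == chrom)
        pos = truth_pos[t_rows]
        c_rows = np.flatnonzero(call_chrom == chrom)
        if c_rows.size == 0 or pos.size == 0:
            continue
        m = mid[c_rows]
        idx = np.searchsorted(pos, m)
        left = np.clip(idx - 1, 0, pos.size - 1)
        right = np.clip(idx, 0, pos.size - 1)
        d_left = np.abs(m - pos[left])
        d_right = np.abs(m - pos[right])
        nearest = np.where(d_left <= d_right, left, right)
        dist = np.minimum(d_left, d_right)
        ok = dist <= tolerance
        dyad_of_call[c_rows[ok]] = t_rows[nearest[ok]]
        recovered[t_rows[nearest[ok]]] = True
    recall = recovered.mean() if n_dyads else float("nan")
    precision = (dyad_of_call >= 0).mean() if len(calls) else float("nan")
    return float(recall), float(precision), dyad_of_call


def membership_accuracy(matrix: pd.DataFrame, truth: GroundTruth,
                        dyad_of_call: np.ndarray) -> float:
    """Balanced accuracy of matrix entries vs planted firing on matched calls:
    mean of sensitivity (planted 1s recovered) and specificity (planted 0s
    stayed 0)."""
    matched = np.flatnonzero(dyad_of_call >= 0)
    if matched.size == 0:
        return float("nan")
    pred = matrix.to_numpy()[matched].astype(bool)
    planted = truth.membership[dyad_of_call[matched]].astype(bool)
    tp = np.logical_and(pred, planted).sum()
    tn = np.logical_and(~pred, ~planted).sum()
    pos = planted.sum()
    neg = planted.size - pos
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    return float((sens + spec) / 2.0)


def cluster_recovery_ari(clusters: ClusterResult, truth: GroundTruth) -> float:
    """Adjusted Rand index between recovered and planted mark clusters
    (over the marks that were clustered)."""
    marks = list(clusters.labels.index)
    planted = [truth.mark_clusters[m] for m in marks]
    return float(adjusted_rand_score(planted, clusters.labels.to_numpy()))
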