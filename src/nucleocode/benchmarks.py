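"""Planted-truth benchmarks for every pipeline stage.

Each function builds its own synthetic dataset under the package's
default study conditions, runs the relevant stage(s) from scratch and
returns the measured quantity. They are used both by the test suite and
by ``scripts/acceptance.py``; problem sizes are chosen so the whole set
runs in a few minutes on one CPU (documented in the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import assign_marks, poisson_upper_tail
from .calling import CallParams, call_nucleosomes
from .multiscale import persistence_test
from .pipeline import (cluster_recovery_ari, match_calls, membership_accuracy,
                       run_histone_code)
from .simulate import default_config, simulate_genome_truth, simulate_reads

ORACLE_LAMBDAS = (0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


def poisson_tail_bruteforce(k: int, lam: float) -> float:
    """Independent oracle for the Poisson upper tail: direct pmf summation
    of the lower tail with ``math.fsum``, subtracted from 1."""
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = -lam
    terms = [math.exp(log_term)]
    for i in range(1, k):
        log_term += math.log(lam) - math.log(i)
        terms.append(math.exp(log_term))
    return 1.0 - math.fsum(terms)


def poisson_oracle_error(max_k: int = 50,
                         lambdas=ORACLE_LAMBDAS) -> tuple[float, int]:
    """Worst absolute deviation between the assignment test's tail
    probability and the brute-force oracle over the (k, lambda) grid."""
    worst, n = 0.0, 0
    for lam in lambdas:
        for k in range(max_k + 1):
            worst = max(worst, abs(poisson_upper_tail(k, lam)
                                   - poisson_tail_bruteforce(k, lam)))
            n += 1
    return worst, n


def calibration_benchmark(seed: int = 0, genome_bp: int = 2_000_000,
                          n_marks: int = 10,
                          background_rate: float = 30.0) -> tuple[float, int]:
    """False-assignment rate of the Poisson test on pure background.

    Simulates background-only reads (no firing nucleosomes), evaluates
    ``assign_marks`` on the planted grid of 147-bp nucleosome windows —
    pooled background coverage yields no peaks by design, so the grid
    supplies the >= 1e5 (window, mark) tests the calibration needs — and
    returns the assigned fraction, which should stay at or below the
    nominal 1e-3 (the discrete test is conservative).
    """
    cfg = default_config(n_marks=n_marks, n_clusters=2,
                         chrom_lengths={"chr1": genome_bp},
                         p_in=0.0, p_out=0.0, signal_depth=0.0,
                         background_rate=background_rate, seed=seed)
    truth = simulate_genome_truth(cfg)
    reads = simulate_reads(cfg, truth)
    pos = truth.dyads["pos"].to_numpy()
    windows = pd.DataFrame({
        "chrom": truth.dyads["chrom"],
        "start": pos - 73,
        "end": pos + 74,
    })
    tests, matrix = assign_marks(windows, reads, cfg.chrom_lengths,
                                 marks=cfg.marks)
    n_tests = len(tests)
    return float(tests["assigned"].mean()), n_tests


def recovery_benchmark(seeds=range(5), signal_depth: float = 20.0,
                       params: CallParams = CallParams()) -> tuple[float, float, int]:
    """Nucleosome recovery on the default benchmark: mean recall and
    precision of calls vs planted dyads at +/-40 bp, over seeds."""
    recalls, precisions, n_dyads = [], [], 0
    for seed in seeds:
        cfg = default_config(signal_depth=signal_depth, seed=seed)
        truth = simulate_genome_truth(cfg)
        reads = simulate_reads(cfg, truth)
        calls = call_nucleosomes(reads, cfg.chrom_lengths, params)
        recall, precision, _ = match_calls(calls, truth)
        recalls.append(recall)
        precisions.append(precision)
        n_dyads += truth.n_nucleosomes
    return float(np.mean(recalls)), float(np.mean(precisions)), n_dyads


@dataclass
class CodeRecovery:
    ari: float
    balanced_accuracy: float
    n_nucleosomes: int
    n_marks: int


def code_recovery_benchmark(seeds=range(5)) -> CodeRecovery:
    """End-to-end histone-code recovery: 20 marks in 5 planted clusters on
    2,000 nucleosomes; mean adjusted Rand index between recovered and
    planted mark clusters, plus balanced accuracy of the binary matrix."""
    aris, accs = [], []
    for seed in seeds:
        cfg = default_config(n_marks=20, n_clusters=5,
                             chrom_lengths={"chr1": 400_000},
                             p_in=0.8, p_out=0.05, signal_depth=20.0,
                             seed=seed)
        res = run_histone_code(cfg, k=5)
        aris.append(cluster_recovery_ari(res.clusters, res.truth))
        _, _, dyad_of_call = match_calls(res.calls, res.truth)
        accs.append(membership_accuracy(res.matrix, res.truth, dyad_of_call))
    return CodeRecovery(ari=float(np.mean(aris)),
                        balanced_accuracy=float(np.mean(accs)),
                        n_nucleosomes=2000, n_marks=20)


@dataclass
class MultiscaleBenchmark:
    agreement_domains: float
    ari_domains: float
    p_value_domains: float
    p_value_free: float
    n_fine_bins: int


def multiscale_benchmark(seed: int = 0, genome_bp: int = 20_000_000,
                         n_permutations: int = 1000) -> MultiscaleBenchmark:
    """Cross-scale persistence at (5 kb, 200 kb): agreement on a
    domain-structured genome (100-kb domains) and the joint-permutation
    p-value on the domain-free control (domain_length = spacing)."""
    results = {}
    for key, dl in [("domains", 100_000), ("free", 200)]:
        cfg = default_config(chrom_lengths={"chrX": genome_bp},
                             signal_depth=5.0, domain_length=dl, seed=seed)
        truth = simulate_genome_truth(cfg)
        reads = simulate_reads(cfg, truth)
        results[key] = persistence_test(
            reads, cfg.chrom_lengths, k=cfg.n_clusters,
            n_permutations=n_permutations, seed=seed + 1)
    dom = results["domains"]
    return MultiscaleBenchmark(
        agreement_domains=dom.observed.correlation_of_correlations,
        ari_domains=dom.observed.cluster_ari,
        p_value_domains=dom.p_value,
        p_value_free=results["free"].p_value,
        n_fine_bins=genome_bp // 5000,
    )


def determinism_check(seed: int = 0) -> bool:
    """Run the full pipeline twice with one seed and verify every stage is
    bit-identical: reads, calls, tests, matrix, correlations, labels."""
    cfg = default_config(chrom_lengths={"chr1": 100_000}, seed=seed)
    a = run_histone_code(cfg)
    b = run_histone_code(cfg)
    return (a.reads.equals(b.reads)
            and a.calls.equals(b.calls)
            and a.tests.equals(b.tests)
            and a.matrix.equals(b.matrix)
            and a.correlation.values.equals(b.correlation.values)
            and a.clusters.labels.equals(b.clusters.labels)
            and a.clusters.leaf_order == b.clusters.leaf_order)
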