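"""Synthetic ChIP-seq generator: planted truth, read statistics, round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nucleocode as nc


def tiny_config(**kw):
    defaults = dict(chrom_lengths={"chrA": 20_000}, seed=1)
    defaults.update(kw)
    return nc.default_config(**defaults)


class TestGroundTruth:
    def test_dyad_count_and_spacing(self):
        cfg = nc.default_config(chrom_lengths={"chr1": 200_000}, spacing=200)
        truth = nc.simulate_genome_truth(cfg)
        assert truth.n_nucleosomes == 1000
        pos = truth.dyads["pos"].to_numpy()
        assert pos[0] == 100
        assert np.all(np.diff(pos) == 200)

    def test_degenerate_probabilities_give_exact_membership(self):
        cfg = tiny_config(p_in=1.0, p_out=0.0)
        truth = nc.simulate_genome_truth(cfg)
        cluster = np.array([cfg.cluster_partition[m] for m in cfg.marks])
        expected = (truth.states[:, None] == cluster[None, :]).astype(np.uint8)
        assert np.array_equal(truth.membership, expected)

    def test_seeded_determinism_truth_and_reads(self):
        cfg = tiny_config(seed=42)
        t1, t2 = nc.simulate_genome_truth(cfg), nc.simulate_genome_truth(cfg)
        assert t1 == t2
        r1, r2 = nc.simulate_reads(cfg, t1), nc.simulate_reads(cfg, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_mean_run_length_tracks_domain_length(self):
        cfg = nc.default_config(chrom_lengths={"chr1": 4_000_000},
                                domain_length=10_000, seed=5)
        truth = nc.simulate_genome_truth(cfg)
        runs = np.diff(np.flatnonzero(np.diff(truth.states) != 0))
        # mean run ~ 50 nucleosomes (10 kb / 200 bp); loose 25% band
        assert 35 < runs.mean() < 65

    def test_states_independent_of_membership_when_p_in_equals_p_out(self):
        # Fisher-combined chi-square over 5 seeds at alpha = 0.01
        pvals = []
        for seed in range(5):
            cfg = nc.default_config(chrom_lengths={"chr1": 2_000_000},
                                    p_in=0.3, p_out=0.3, seed=seed)
            truth = nc.simulate_genome_truth(cfg)
            assert truth.n_nucleosomes == 10_000
            table = pd.crosstab(truth.states, truth.membership[:, 0])
            pvals.append(stats.chi2_contingency(table).pvalue)
        combined = stats.combine_pvalues(pvals, method="fisher").pvalue
        assert combined > 0.01

    @pytest.mark.parametrize("bad", [
        dict(p_in=1.5), dict(p_out=-0.1), dict(spacing=20, read_length=36),
        dict(domain_length=100), dict(chrom_lengths={"c": 100}),
        dict(signal_depth=-1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(nc.ConfigError):
            tiny_config(**bad)

    def test_cluster_labels_must_cover_range(self):
        with pytest.raises(nc.ConfigError):
            nc.SimConfig(chrom_lengths={"c": 10_000},
                         cluster_partition={"a": 1, "b": 3})


class TestReads:
    def test_all_rates_zero_yields_no_reads(self):
        cfg = tiny_config(signal_depth=0.0, background_rate=0.0)
        truth = nc.simulate_genome_truth(cfg)
        reads = nc.simulate_reads(cfg, truth)
        assert len(reads) == 0

    def test_reads_lie_within_chromosome_with_fixed_length(self):
        cfg = tiny_config(jitter_sd=50.0, seed=9)
        truth = nc.simulate_genome_truth(cfg)
        reads = nc.simulate_reads(cfg, truth)
        assert (reads["start"] >= 0).all()
        assert (reads["end"] <= 20_000).all()
        assert ((reads["end"] - reads["start"]) == cfg.read_length).all()
        assert reads["start"].is_monotonic_increasing

    def test_total_read_count_matches_expectation_over_seeds(self):
        # Monte-Carlo over 20 seeds: mean total within 3 MC standard errors
        totals, expectations = [], []
        for seed in range(20):
            cfg = tiny_config(seed=seed, signal_depth=5.0, background_rate=1.0)
            truth = nc.simulate_genome_truth(cfg)
            reads = nc.simulate_reads(cfg, truth)
            totals.append(len(reads))
            expectations.append(truth.membership.sum() * cfg.signal_depth
                                + cfg.background_rate * 20.0 * cfg.n_marks)
        diff = np.array(totals) - np.array(expectations)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se + 1e-9

    def test_strand_fraction_within_exact_binomial_interval(self):
        cfg = nc.default_config(chrom_lengths={"chr1": 200_000}, seed=2)
        truth = nc.simulate_genome_truth(cfg)
        reads = nc.simulate_reads(cfg, truth)
        n = len(reads)
        fwd = int((reads["strand"] == "+").sum())
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= fwd <= hi


class TestTruthRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        cfg = tiny_config(seed=4)
        truth = nc.simulate_genome_truth(cfg)
        nc.write_truth(truth, tmp_path)
        assert nc.read_truth(tmp_path) == truth

    def test_empty_truth_round_trips(self, tmp_path):
        truth = nc.GroundTruth(
            dyads=pd.DataFrame({"chrom": pd.Series([], dtype=object),
                                "pos": np.zeros(0, np.int64)}),
            states=np.zeros(0, np.int64),
            membership=np.zeros((0, 2), np.uint8),
            marks=["a", "b"], mark_clusters={"a": 1, "b": 1})
        nc.write_truth(truth, tmp_path)
        back = nc.read_truth(tmp_path)
        assert back.n_nucleosomes == 0
        assert back.marks == ["a", "b"]
        assert back.mark_clusters == truth.mark_clusters

    def test_dyad_bed_is_sorted_half_open_single_base(self, tmp_path):
        cfg = tiny_config(seed=6)
        truth = nc.simulate_genome_truth(cfg)
        nc.write_truth(truth, tmp_path)
        bed = nc.io.read_bed6(tmp_path / "dyads.bed")
        assert ((bed["end"] - bed["start"]) == 1).all()
        for _, sub in bed.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing
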