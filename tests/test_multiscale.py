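"""Binned densities and cross-scale agreement of mark associations."""

import numpy as np
import pandas as pd
import pytest

import nucleocode as nc

from conftest import make_reads


def uniform_reads(rng, n, mark, length, chrom="c"):
    starts = rng.integers(0, length - 36, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return [(chrom, int(s), int(s) + 36, mark, st)
            for s, st in zip(starts, strands)]


class TestBinReads:
    def test_reads_in_first_window_land_in_first_bin(self):
        reads = make_reads([("c", 100 * i, 100 * i + 36, "m", "+")
                            for i in range(10)])
        dens = nc.bin_reads(reads, {"c": 50_000}, 5000)
        row = dens.counts.loc["m"].to_numpy()
        assert row[0] == 10 and row[1:].sum() == 0

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        reads = make_reads(uniform_reads(rng, 500, "m", 100_000))
        dens = nc.bin_reads(reads, {"c": 100_000}, 7000)
        assert dens.counts.loc["m"].sum() == 500

    def test_refinement_consistency_on_halving(self):
        rng = np.random.default_rng(1)
        reads = make_reads(uniform_reads(rng, 800, "m", 80_000))
        fine = nc.bin_reads(reads, {"c": 80_000}, 2000)
        coarse = nc.bin_reads(reads, {"c": 80_000}, 4000)
        np.testing.assert_array_equal(
            fine.counts.to_numpy().reshape(1, -1, 2).sum(axis=2),
            coarse.counts.to_numpy())

    def test_five_prime_position_is_strand_aware(self):
        # reverse read straddling a bin boundary counts in its 3'-coordinate bin
        reads = make_reads([("c", 4980, 5016, "m", "-"),
                            ("c", 4980, 5016, "m", "+")])
        dens = nc.bin_reads(reads, {"c": 20_000}, 5000)
        assert dens.counts.loc["m", 0] == 1  # forward 5' = 4980
        assert dens.counts.loc["m", 1] == 1  # reverse 5' = 5015

    def test_bins_tile_chromosomes_half_open(self):
        dens = nc.bin_reads(make_reads([]), {"a": 12_500, "b": 5_000}, 5000)
        assert list(dens.bins["end"] - dens.bins["start"]) == [5000, 5000, 2500, 5000]

    def test_invalid_bin_size_rejected(self):
        with pytest.raises(ValueError):
            nc.bin_reads(make_reads([]), {"c": 1000}, 0)

    def test_aggregate_equals_direct_coarse_binning(self):
        rng = np.random.default_rng(2)
        reads = make_reads(uniform_reads(rng, 2000, "m", 1_000_000)
                           + uniform_reads(rng, 1500, "n", 1_000_000))
        fine = nc.bin_reads(reads, {"c": 1_000_000}, 5000)
        agg = nc.aggregate_bins(fine, 40)
        direct = nc.bin_reads(reads, {"c": 1_000_000}, 200_000)
        np.testing.assert_array_equal(agg.counts.to_numpy(),
                                      direct.counts.to_numpy())
        pd.testing.assert_frame_equal(agg.bins, direct.bins)


class TestCorrelationAtScale:
    def test_identical_positions_correlate_perfectly_at_any_scale(self):
        rng = np.random.default_rng(3)
        recs = uniform_reads(rng, 400, "m", 200_000)
        twin = [(c, s, e, "n", st) for c, s, e, _, st in recs]
        reads = make_reads(recs + twin)
        for bin_size in (1000, 10_000, 50_000):
            corr = nc.correlation_at_scale(nc.bin_reads(reads, {"c": 200_000},
                                                        bin_size))
            assert corr.values.loc["m", "n"] == pytest.approx(1.0)

    def test_independent_uniform_marks_within_null_bound(self):
        # |r| should stay below the 99% null bound 2.58/sqrt(n_bins)
        rng = np.random.default_rng(4)
        length, n_bins = 10_000_000, 10_000
        reads = make_reads(uniform_reads(rng, 20_000, "m", length)
                           + uniform_reads(rng, 20_000, "n", length))
        corr = nc.correlation_at_scale(nc.bin_reads(reads, {"c": length},
                                                    length // n_bins))
        assert abs(corr.values.loc["m", "n"]) < 2.58 / np.sqrt(n_bins)

    def test_marks_on_disjoint_halves_anticorrelate(self):
        rng = np.random.default_rng(5)
        left = uniform_reads(rng, 300, "m", 50_000)
        right = [("c", s + 50_000, e + 50_000, "n", st)
                 for _, s, e, _, st in uniform_reads(rng, 300, "n", 50_000)]
        corr = nc.correlation_at_scale(
            nc.bin_reads(make_reads(left + right), {"c": 100_000}, 10_000))
        assert corr.values.loc["m", "n"] < 0

    def test_constant_rows_flagged(self):
        reads = make_reads([("c", 100, 136, "m", "+")])
        dens = nc.bin_reads(reads, {"c": 10_000}, 1000,
                            marks=["m", "silent"])
        corr = nc.correlation_at_scale(dens)
        assert not corr.defined["silent"]
        assert np.isnan(corr.values.loc["m", "silent"])


class TestCrossScaleAgreement:
    def _corr(self, mat, names):
        return nc.MarkCorrelationMatrix(
            values=pd.DataFrame(mat, index=names, columns=names),
            defined=pd.Series(True, index=names))

    def test_identical_matrices_agree_perfectly(self):
        names = list("abcd")
        r = np.array([[1.0, 0.8, -0.2, -0.3], [0.8, 1.0, -0.1, -0.2],
                      [-0.2, -0.1, 1.0, 0.7], [-0.3, -0.2, 0.7, 1.0]])
        agr = nc.cross_scale_agreement(self._corr(r, names),
                                       self._corr(r.copy(), names), k=2)
        assert agr.correlation_of_correlations == pytest.approx(1.0)
        assert agr.cluster_ari == pytest.approx(1.0)

    def test_negated_matrix_gives_minus_one(self):
        names = list("abcd")
        rng = np.random.default_rng(6)
        r = rng.uniform(-0.5, 0.9, size=(4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        neg = -r.copy()
        np.fill_diagonal(neg, 1.0)
        agr = nc.cross_scale_agreement(self._corr(r, names),
                                       self._corr(neg, names), k=2)
        assert agr.correlation_of_correlations == pytest.approx(-1.0)

    def test_symmetric_in_the_two_scales(self):
        names = list("abcde")
        rng = np.random.default_rng(7)
        def rand_corr():
            x = rng.normal(size=(5, 30))
            return self._corr(np.corrcoef(x), names)
        a, b = rand_corr(), rand_corr()
        ab = nc.cross_scale_agreement(a, b, k=2)
        ba = nc.cross_scale_agreement(b, a, k=2)
        assert ab.correlation_of_correlations == pytest.approx(
            ba.correlation_of_correlations)
        assert ab.cluster_ari == pytest.approx(ba.cluster_ari)

    def test_undefined_marks_excluded_pairwise(self):
        names = list("abc")
        r = np.eye(3)
        fine = self._corr(r, names)
        coarse = self._corr(r.copy(), names)
        coarse.defined["c"] = False
        coarse.values.loc["c", :] = np.nan
        coarse.values.loc[:, "c"] = np.nan
        agr = nc.cross_scale_agreement(fine, coarse, k=1)
        assert agr.marks == ["a", "b"]


@pytest.fixture(scope="module")
def sims():
    out = {}
    for key, dl in [("domains", 100_000), ("free", 200)]:
        cfg = nc.default_config(chrom_lengths={"chrX": 4_000_000},
                                signal_depth=5.0, domain_length=dl, seed=7)
        truth = nc.simulate_genome_truth(cfg)
        out[key] = (cfg, nc.simulate_reads(cfg, truth))
    return out


class TestPersistence:

    def test_domain_structure_gives_high_agreement(self, sims):
        cfg, reads = sims["domains"]
        res = nc.persistence_test(reads, cfg.chrom_lengths, k=4,
                                  fine_size=5000, coarse_size=200_000,
                                  n_permutations=100, seed=1)
        assert res.observed.correlation_of_correlations >= 0.8

    def test_domain_free_control_matches_joint_null(self, sims):
        cfg, reads = sims["free"]
        res = nc.persistence_test(reads, cfg.chrom_lengths, k=4,
                                  fine_size=5000, coarse_size=200_000,
                                  n_permutations=200, seed=2)
        assert res.p_value >= 0.05

    def test_independent_null_detects_shared_structure(self, sims):
        # the per-mark shuffle destroys co-occurrence, so even the
        # domain-free data rejects it: it is not a higher-order null
        cfg, reads = sims["free"]
        res = nc.persistence_test(reads, cfg.chrom_lengths, k=4,
                                  fine_size=5000, coarse_size=200_000,
                                  n_permutations=100, seed=3,
                                  mode="independent")
        assert res.p_value < 0.05

    def test_permutation_test_deterministic_given_seed(self, sims):
        cfg, reads = sims["domains"]
        kw = dict(k=4, fine_size=5000, coarse_size=200_000,
                  n_permutations=30, seed=9)
        r1 = nc.persistence_test(reads, cfg.chrom_lengths, **kw)
        r2 = nc.persistence_test(reads, cfg.chrom_lengths, **kw)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null, r2.null)

    def test_incompatible_scales_rejected(self, sims):
        cfg, reads = sims["free"]
        with pytest.raises(ValueError):
            nc.persistence_test(reads, cfg.chrom_lengths, k=4,
                                fine_size=5000, coarse_size=12_345)
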