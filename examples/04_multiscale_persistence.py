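"""Do nucleosome-level mark associations persist at higher folding orders?

Bins reads at 5 kb and 200 kb on a genome with 100-kb chromatin domains,
compares the two scales' mark-correlation matrices
(correlation-of-correlations and cluster ARI) and tests significance
against the joint-permutation null; a domain-free control (independent
nucleosome states) shows what the null looks like when only
nucleosome-level co-occurrence is present.
"""

import nucleocode as nc

for label, domain_length in [("100-kb domains", 100_000),
                             ("domain-free control", 200)]:
    config = nc.default_config(chrom_lengths={"chrX": 10_000_000},
                               signal_depth=5.0, domain_length=domain_length,
                               seed=0)
    truth = nc.simulate_genome_truth(config)
    reads = nc.simulate_reads(config, truth)
    res = nc.persistence_test(reads, config.chrom_lengths,
                              k=config.n_clusters, n_permutations=500, seed=1)
    o = res.observed
    print(f"{label}:")
    print(f"  agreement (r of r) : {o.correlation_of_correlations:.3f}"
          f"  cluster ARI: {o.cluster_ari:.3f}")
    print(f"  permutation p      : {res.p_value:.3f}  ({res.mode} null)")
# High agreement in both conditions shows that nucleosome-level
# co-occurrence alone propagates to coarse bins; only the domain-free
# p-value stays at chance, because the joint null keeps co-occurrence
# and destroys the spatial domain arrangement.
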