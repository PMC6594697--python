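# nucleocode

Detecting the combinatorial structure of histone modifications — the
"histone code" — at single-nucleosome resolution, and asking whether the
associations found there persist at higher orders of chromatin folding.

The package is a self-contained, seeded implementation of the analysis a
chromatin biologist would run on a large multi-mark ChIP-seq collection
(e.g. dozens of histone marks in one cell type), plus a synthetic
ChIP-seq generator with planted ground truth so every stage can be
scored. It is aimed at computational epigenomics researchers who want a
tested, reproducible version of the nucleosome-level co-occurrence
pipeline or a benchmark harness for variants of it.

## The method

1. **Read model.** Mapped reads of all marks are pooled; each 36-nt read
   is extended to 150 nt from its 5' end and the central 75 nt are kept,
   giving a per-base coverage track centred on nucleosome dyads.
2. **Nucleosome calling.** Candidate peaks are maximal runs of coverage
   ≥ *h* (runs separated by < *g* sub-threshold bases are merged).
   Peaks with significantly uneven strand counts (exact two-sided
   binomial test against 1/2) are removed, as are peaks narrower than
   80 nt or wider than 250 nt.
3. **Mark assignment.** For nucleosome *i* and mark *m*, the observed
   read count *k* is compared with the uniform chromosome-wide
   expectation λ = (mark reads on chromosome) · width / chromosome
   length via the Poisson upper tail P(X ≥ k); p < 10⁻³ sets entry
   B[i, m] = 1 of the **binary assignment matrix**.
4. **Histone-code clustering.** Pairwise phi coefficients (Pearson on
   binary columns) give an M × M mark correlation matrix; complete-
   linkage hierarchical clustering on distance 1 − r, cut at *k*
   clusters, partitions the marks.
5. **Multi-scale persistence.** Reads are binned at 5 kb and 200 kb;
   mark-density correlation matrices at the two scales are compared by
   the correlation of their upper triangles and the adjusted Rand index
   of their k-cluster partitions, with significance from a permutation
   null that preserves nucleosome-level co-occurrence (see
   `docs/methods.md`).

## Worked example

`examples/03_cluster_histone_code.py` plants 5 clusters of 20 marks on
2,000 nucleosomes and recovers them end to end:

```
nucleosome calls   : 1928
recovered clusters : k = 5
adjusted Rand index: 1.000 vs the planted mark partition
  cluster 1: M01 M02 M03 M04
  cluster 2: M05 M06 M07 M08
  cluster 3: M09 M10 M11 M12
  cluster 4: M13 M14 M15 M16
  cluster 5: M17 M18 M19 M20
```

1,928 of the 2,000 planted nucleosomes survive calling (the exact
strand test removes ~5% of true peaks at α = 0.05), and the adjusted
Rand index of 1.0 means the phi-correlation + clustering step put every
mark back into its planted cluster. The other examples cover simulation
and calling (`01`), the Poisson assignment matrix (`02`) and the
multi-scale persistence test with its domain-free control (`04`).

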