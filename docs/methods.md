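# Methods

This note documents the models, defaults and design choices behind
`nucleocode`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Synthetic ChIP-seq generator

The generator emulates a multi-mark ChIP-seq collection over a genome of
regularly spaced nucleosomes.

**Nucleosome grid.** Dyads are placed deterministically at
`spacing/2 + i·spacing` (default repeat length 200 bp, the canonical
~147 bp core plus linker). Real nucleosomes are irregularly spaced and
partially phased; the regular grid is deliberate, because it makes
recall/precision against planted dyads unambiguous.

**Chromatin states.** Each nucleosome carries one of K states. States
follow a run-length process: at each nucleosome the state is resampled
uniformly over all K labels with probability
`min(1, (spacing/domain_length)·K/(K−1))`, giving geometric runs with
mean length `domain_length/spacing` nucleosomes when uncapped. The
resample-over-all-labels form (rather than switch-to-a-different-label)
was chosen so that the domain-free limit `domain_length = spacing`
degenerates to exactly independent states — the correct null for the
multi-scale control; a forced-switch process would instead make
neighbouring states anti-correlated.

**Mark firing.** Mark m belongs to one planted cluster; it fires on a
nucleosome with probability `p_in` (default 0.8) when the nucleosome's
state matches the mark's cluster and `p_out` (default 0.05) otherwise.
Defaults give clearly block-structured but noisy co-occurrence,
comparable to what strong point-source marks show in practice.

**Reads.** Each firing (nucleosome, mark) pair sheds
`Poisson(signal_depth)` reads (default 20 — deep, modern coverage for a
point-source mark). Per read, a 147-bp fragment is centred at
`dyad + N(0, jitter_sd)` (default 15 bp, approximating MNase/sonication
positional scatter), the strand is a fair coin and the 36-nt read is
taken from the fragment's 5' end on its strand, so the downstream 150-nt
extension convention recovers the fragment. Background reads are uniform
per mark at `background_rate` per kb (default 0.1). Reads are shifted,
never truncated, at chromosome edges, preserving the fixed read length.
Not modelled: sequence composition, GC/mappability bias, duplicate
artefacts, fragment-size variability. Benchmarks passing here therefore
show correctness of the *computation*, not robustness to those real-data
artefacts.

**Reproducibility.** All randomness derives from the single config seed;
truth and reads use two child streams of that seed so the two stages can
be (re)generated independently while remaining bit-identical run to run.

## Read model and nucleosome calling

Reads are extended to 150 nt from their 5' end and the central 75 nt
kept; pooled per-base coverage of these central segments over all marks
is the calling signal. The central-segment offset is `floor((L−75)/2)`
(37 for a full fragment); rounding had to be fixed one way, floor is
documented and tested. Edge-clipped fragments shorter than 75 nt are
kept whole rather than discarded, preserving coverage mass.

Candidate peaks are maximal runs of coverage ≥ `min_height` (default 5),
with runs separated by fewer than `min_gap` (default 30) sub-threshold
bases merged; the summit is the leftmost maximum. This thresholded-run
detector is a deliberately simple, fully specified stand-in for a
published nucleosome positioner whose edge-detection internals are not
reproduced here; it is scored directly against planted dyads (recall and
precision ≥ 0.9 at ±40 bp under the default conditions, and in practice
≈ 0.96/1.0).

Two post-detection filters follow the published strategy:

- **Strand evenness.** Both strands of a genuine nucleosome should be
  sequenced evenly. We use the exact two-sided binomial test of forward
  reads among all reads overlapping the peak at success probability 1/2
  (`p = min(1, 2·P(X ≤ min(f, r)))`, p = 1 for zero reads), removing
  peaks with p < α = 0.05. The published description says only
  "significantly different"; the test and α are explicit configuration.
  At α = 0.05 this intentionally sacrifices ~5% of true peaks.
- **Width.** Peaks narrower than 80 nt or wider than 250 nt are removed;
  bounds are inclusive on the keep side (80 and 250 survive), reading
  the removal rule literally.

The filters commute (both are per-peak predicates), and every emitted
call satisfies the width bounds by construction.

## Poisson mark assignment

For each (call, mark) pair: observed count k, expectation
λ = (mark's chromosome total) · width / chromosome length, upper tail
p = P(X ≥ k) under Poisson(λ), assignment iff p < 10⁻³ (strict).
Degenerate cases: k = 0 → p = 1; λ = 0 with k > 0 → p = 0 (assigned).
No multiple-testing correction is applied — the published procedure
thresholds raw per-test p-values.

**Counting rule.** A read counts toward a peak when its inferred
fragment centre (the midpoint of its 150-nt extension, equivalently of
its central segment) lies inside the peak. The alternative — any-overlap
of the 75-nt segment — effectively widens every peak by ~74 bp, so
E[k] ≈ λ·(width+74)/width under uniformity and the test becomes
anti-conservative by an order of magnitude. Centre-counting makes the
length-proportional λ exact under uniformity; on pure background the
measured false-assignment fraction is ~6×10⁻⁴ over 10⁵ tests, below the
nominal 10⁻³ (the discrete test is conservative). The calibration
benchmark evaluates the test on a planted grid of 147-bp windows,
because background-only coverage yields no peaks to call — the quantity
being calibrated is the assignment test, not the caller.

## Histone-code clustering

Phi coefficients (Pearson on binary columns) over the assignment matrix
give the M × M mark correlation matrix. Constant columns have undefined
correlation; they are flagged and excluded from clustering with a
report, never imputed or zeroed — imputation would fabricate structure.
Clustering is agglomerative with complete linkage (the default of the
standard hierarchical-clustering tool this reproduces) on distance
1 − r, cut at k clusters; k defaults to the planted cluster number in
benchmarks and is never auto-selected. Labels are relabelled by first
appearance in column order and the dendrogram leaf order is exposed for
corrplot-style matrix display, so results are deterministic including
tie-breaks.

## Multi-scale persistence

Reads are binned by 5' position at a fine and a coarse scale (defaults
5 kb and 200 kb, the extreme browser-zoom ranges the visual argument
used); mark-density correlation matrices are computed at each scale, and
cross-scale agreement is summarised by (a) the Pearson correlation of
the two matrices' vectorised upper triangles and (b) the adjusted Rand
index of the two k-cluster partitions. These statistics are this
package's formalisation of what was originally a visual browser-track
comparison.

**Permutation null (a substantive design point).** Aggregating
independent, identically distributed per-bin count vectors leaves
cross-mark correlation exactly unchanged at every bin size, so
nucleosome-level co-occurrence alone already produces strong cross-scale
agreement — domains are not needed for it (we measure r-of-r ≈ 0.9 even
with independent per-nucleosome states). A null that destroys all
cross-mark structure (shuffling bins independently per mark) is
therefore rejected in *every* condition and cannot isolate higher-order
organisation; it is provided as `mode="independent"` for completeness.
The default `mode="joint"` null applies one permutation of the fine bins
— shared by all marks, within each chromosome — before coarse
aggregation: the fine-scale matrix is exactly invariant, co-occurrence
is preserved, and only the spatial arrangement of bins is destroyed.
Under the domain-free generator the fine-bin vectors are exchangeable,
so the joint-null p-value is uniform and the control behaves as a true
null; with 100-kb domains the observed coarse-scale structure exceeds
the shuffled one. The reported p-value uses the r-of-r statistic with
the +1 permutation correction (1,000 permutations by default,
seed-controlled).

## Problem sizes and numerical choices

Benchmarks run on one CPU in a few minutes total: recovery uses five
seeds of a 500-kb genome (2,500 nucleosomes each); the five-cluster
recovery uses 20 marks on 400 kb (2,000 nucleosomes, p_in 0.8, p_out
0.05, depth 20), five seeds; calibration uses 10⁵ (window, mark) tests
on a 2-Mb background-only genome at 30 reads/kb/mark; the multi-scale
benchmark uses a 20-Mb chromosome (4,000 fine bins, 100 coarse bins,
depth 5) with 1,000 permutations. Correlations are clipped to [−1, 1]
against floating-point drift; condensed distances are symmetrised before
linkage; all sorts use stable keys so outputs are bit-identical for a
fixed seed.

## Known limitations

- The caller is a stand-in: it reproduces the published *filters*
  exactly but not any particular positioner's peak boundaries.
- λ uses a chromosome-wide uniform background; no local background or
  input subtraction (deliberately, matching the described procedure).
- The regular nucleosome grid and independent-mark background make the
  synthetic benchmarks easier than real chromatin; passing them
  validates the machinery and its calibration, not performance on real
  CD4 T-cell-scale data.
- The multi-scale agreement statistic is one defensible quantification
  of "associations persist across scales"; other operationalizations
  (e.g. explicit variance decomposition across scales) are possible.
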