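"""Assign histone marks to called nucleosomes with the Poisson test.

Each (nucleosome, mark) pair is tested: observed reads in the peak vs
the chromosome-wide uniform expectation; p < 1e-3 sets a 1 in the
binary assignment matrix.
"""

import nucleocode as nc

config = nc.default_config(chrom_lengths={"chr1": 100_000}, seed=0)
truth = nc.simulate_genome_truth(config)
reads = nc.simulate_reads(config, truth)
calls = nc.call_nucleosomes(reads, config.chrom_lengths)
tests, matrix = nc.assign_marks(calls, reads, config.chrom_lengths,
                                marks=config.marks)

recall, precision, dyad_of_call = nc.match_calls(calls, truth)
acc = nc.membership_accuracy(matrix, truth, dyad_of_call)
print(f"binary matrix        : {matrix.shape[0]} nucleosomes x {matrix.shape[1]} marks")
print(f"assigned entries     : {matrix.to_numpy().mean():.3f} of all pairs")
print(f"balanced accuracy    : {acc:.3f} vs planted firing on matched calls")
print("first rows of the matrix:")
print(matrix.head(3).to_string())
# Balanced accuracy near 1 means Poisson-significant entries recover the
# planted mark firing almost perfectly at depth 20.
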