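import numpy as np
import pandas as pd
import pytest

import nucleocode as nc


@pytest.fixture(scope="session")
def small_config():
    """Small but realistic study conditions: 100 kb, 500 nucleosomes."""
    return nc.default_config(chrom_lengths={"chr1": 100_000}, seed=3)


@pytest.fixture(scope="session")
def small_run(small_config):
    return nc.run_histone_code(small_config)


def make_reads(records):
    """Build a BED6 reads frame from (chrom, start, end, mark, strand) tuples."""
    return pd.DataFrame(
        [(c, s, e, m, 0, st) for c, s, e, m, st in records],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    ).astype({"start": np.int64, "end": np.int64})
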