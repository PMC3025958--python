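import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ercross.genomic_io import ChromSizes, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20110114)


@pytest.fixture
def toy_sizes():
    return ChromSizes.from_mapping({"chr1": 100_000, "chr2": 100_000})


def random_intervals(rng, n, chrom_lens, max_len=400, with_ids=True):
    """Shared helper: n random intervals on the given toy genome."""
    chroms = sorted(chrom_lens)
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_lens[chrom] - length))
        out.append(
            GenomicInterval(
                chrom, start, start + length, id=f"iv_{i:04d}" if with_ids else None
            )
        )
    return out
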