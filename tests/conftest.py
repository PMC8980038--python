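import numpy as np
import pandas as pd
import pytest

from atacburst.fragments import GenomeBinning


@pytest.fixture
def small_binning() -> GenomeBinning:
    """Two tiny chromosomes, 100-bp bins (chr1 ends on a partial bin)."""
    return GenomeBinning({"chr1": 10_050, "chr2": 5_000}, bin_width=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_fragments(
    rng: np.random.Generator, binning: GenomeBinning, n: int, max_len: int = 600
) -> pd.DataFrame:
    """Random valid fragments across the binning's chromosomes."""
    chroms = list(binning.chrom_sizes)
    ci = rng.integers(len(chroms), size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    sizes = np.array([binning.chrom_sizes[c] for c in chroms])[ci]
    lengths = np.minimum(lengths, sizes)
    starts = (rng.random(n) * (sizes - lengths)).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
        }
    )
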