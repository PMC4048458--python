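import numpy as np
import pytest

from genedist.recmap import ChromBins, RecombinationMap, standardize


def make_map(rates_by_chrom: dict[str, list[float]], bin_width: int = 10_000,
             start: int = 0) -> RecombinationMap:
    """Build a gap-free map from per-chromosome rate lists."""
    bins = {}
    for chrom, rates in rates_by_chrom.items():
        starts = np.arange(start, start + len(rates) * bin_width, bin_width, dtype=np.int64)
        bins[chrom] = ChromBins(
            starts=starts, ends=starts + bin_width,
            rate=np.asarray(rates, dtype=float),
        )
    return RecombinationMap(bins=bins, bin_width=bin_width)


@pytest.fixture
def uniform_map():
    """100 bins of constant rate on chr1; after standardization all SRR = 1."""
    return standardize(make_map({"chr1": [1.0] * 100}))
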