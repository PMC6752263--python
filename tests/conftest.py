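import numpy as np
import pytest

from cnvinterp.core import GenomeLayout, Interval
from cnvinterp.depth import ChromBins, NormalizedProfile


@pytest.fixture
def layout():
    """Kilobase-scale toy genome with both sex chromosomes."""
    return GenomeLayout.from_dict(
        {"chr1": 500_000, "chr2": 400_000, "chrX": 300_000, "chrY": 100_000}
    )


@pytest.fixture
def autosomal_layout():
    return GenomeLayout.from_dict({"chr1": 500_000, "chr2": 400_000})


def make_normalized(layout, values_by_chrom, bin_width=1000, sex="female"):
    """Build a NormalizedProfile directly from copy-value arrays."""
    bins = {}
    for chrom, vals in values_by_chrom.items():
        vals = np.asarray(vals, dtype=float)
        starts = np.arange(len(vals), dtype=np.int64) * bin_width
        ends = starts + bin_width
        bins[chrom] = ChromBins(starts, ends, vals)
    return NormalizedProfile(layout, bins, sex=sex, norm_constant=1.0)


@pytest.fixture
def make_profile(layout):
    def _make(values_by_chrom, **kw):
        return make_normalized(layout, values_by_chrom, **kw)

    return _make
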