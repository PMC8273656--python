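import numpy as np
import pytest

from cbcnv.preprocess import BinProfile, SegmentProfile


def make_bin_profile(depth, gc=None, bin_size=2000, chrom="chr21", masked=None):
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    starts = np.arange(n, dtype=np.int64) * bin_size
    if gc is None:
        gc = np.full(n, 0.45)
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    return BinProfile(
        chrom=chrom,
        bin_size=bin_size,
        start=starts,
        end=starts + bin_size,
        read_depth=depth,
        gc_fraction=np.asarray(gc, dtype=float),
        n_masked=np.asarray(masked, dtype=bool),
    )


def make_segments(values, n_bins=None, bin_size=2000, chrom="chr21"):
    """A SegmentProfile with the given per-segment values and bin counts."""
    values = np.asarray(values, dtype=float)
    k = len(values)
    if n_bins is None:
        n_bins = np.ones(k, dtype=np.int64)
    n_bins = np.asarray(n_bins, dtype=np.int64)
    last = np.cumsum(n_bins) - 1
    first = last - n_bins + 1
    return SegmentProfile(
        chrom=chrom,
        first_bin=first,
        last_bin=last,
        start=first * bin_size,
        end=(last + 1) * bin_size,
        value=values,
        n_bins=n_bins,
        bin_values=np.repeat(values, n_bins),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
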