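import numpy as np
import pandas as pd
import pytest

from chromdyn.intervals_io import Interval, PeakSet


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_width=200, named=True):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(Interval(chrom, start, start + width,
                            name=f"iv_{i}" if named else "."))
    return out


def brute_force_overlap(a: Interval, b: Interval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def timecourse_results():
    """Shared five-timepoint study (2,000 elements) used by several tests."""
    from chromdyn.pipeline import run_timecourse_study

    return run_timecourse_study(101)


@pytest.fixture(scope="session")
def differential_results():
    from chromdyn.pipeline import run_differential_study

    return run_differential_study(11)
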