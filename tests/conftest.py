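import numpy as np
import pandas as pd
import pytest

from sescreen import ExpressionMatrix, GenomicInterval, IntervalSet, SignalTrack


@pytest.fixture
def toy_expr():
    """3 genes x 3 tissues (1 sample each): g1 specific to t1, g3 to t2."""
    values = pd.DataFrame(
        {"s1": [10.0, 5.0, 1.0], "s2": [1.0, 5.0, 10.0], "s3": [1.0, 5.0, 1.0]},
        index=["g1", "g2", "g3"],
    )
    groups = pd.Series({"s1": "t1", "s2": "t2", "s3": "t3"})
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def small_genome():
    return {"chr1": 10_000, "chr2": 5_000}


@pytest.fixture
def constant_track(small_genome):
    track = SignalTrack.zeros(small_genome, bin_width=50)
    for chrom in track.values:
        track.values[chrom][:] = 2.0
    return track


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


def brute_force_overlaps(a, b, min_overlap_bp=1):
    """All-pairs reference for interval overlap queries."""
    return [
        sorted(u for u in b if iv.overlap_length(u) >= min_overlap_bp) for iv in a
    ]
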