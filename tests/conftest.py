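import itertools

import numpy as np
import pytest

from clotburden import SEGMENTS, SegmentStatus


@pytest.fixture(scope="session")
def all_statuses():
    """All 2^7 = 128 possible segment-status combinations."""
    out = []
    for bits in itertools.product((False, True), repeat=len(SEGMENTS)):
        out.append(SegmentStatus(**dict(zip(SEGMENTS, bits))))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_labelled_scores(rng, n=12, n_levels=11):
    """A random integer score vector with both outcome classes present."""
    while True:
        scores = rng.integers(0, n_levels, size=n)
        labels = rng.integers(0, 2, size=n)
        if 1 < labels.sum() < n - 1:
            return scores, labels
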