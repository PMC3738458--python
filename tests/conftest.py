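import numpy as np
import pytest

from rangekit.core import IntegerRanges


def random_pairs(rng: np.random.Generator, n: int, coord_max: int = 10_000,
                 width_max: int = 200, zero_width_frac: float = 0.0):
    """Random (start, end) tuples, optionally salting in zero-width ranges."""
    starts = rng.integers(1, coord_max, size=n)
    widths = rng.integers(1, width_max + 1, size=n)
    if zero_width_frac > 0:
        zw = rng.random(n) < zero_width_frac
        widths[zw] = 0
    return [(int(s), int(s + w - 1)) for s, w in zip(starts, widths)]


def pairs_to_ranges(pairs) -> IntegerRanges:
    return IntegerRanges([p[0] for p in pairs], [p[1] for p in pairs])


def ranges_to_pairs(r: IntegerRanges):
    return list(zip(r.starts.tolist(), r.ends.tolist()))


@pytest.fixture
def rng():
    return np.random.default_rng(20130808)
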