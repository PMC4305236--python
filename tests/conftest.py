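import itertools

import pytest

from mapanchor.map_model import GenomicMap, MapCollection, Marker


def make_collection(markers, weights=None, sizes=None) -> MapCollection:
    """Build a MapCollection from (scaffold, pos, map, lg, map_pos) tuples."""
    collection = MapCollection(scaffold_sizes=dict(sizes or {}))
    for spec in markers:
        collection.add_marker(Marker(*spec))
    if weights:
        collection.apply_weights(weights)
    return collection


def lms_bruteforce(values) -> int:
    """Exhaustive LMS oracle: enumerate all 2^n subsequences."""
    n = len(values)
    best = 0
    for mask in range(1 << n):
        sub = [values[i] for i in range(n) if mask >> i & 1]
        if all(a <= b for a, b in zip(sub, sub[1:])) or all(
            a >= b for a, b in zip(sub, sub[1:])
        ):
            best = max(best, len(sub))
    return best


@pytest.fixture
def two_scaffold_collection():
    return make_collection(
        [
            ("a", 0, "M", "1", 1.0),
            ("a", 10, "M", "1", 2.0),
            ("b", 0, "M", "1", 3.0),
            ("b", 10, "M", "1", 4.0),
        ]
    )
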