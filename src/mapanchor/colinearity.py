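"""Colinearity objective: longest monotonic subsequence and the weighted
configuration score L.

A scaffold configuration is scored per map track (map, linkage group): the
markers of each scaffold are concatenated in configuration order (ascending
physical position for forward scaffolds, descending for reversed ones) and
the length of the longest monotonic subsequence (LMS) of the resulting map
positions is taken.  L is the weight-summed LMS over all tracks.

Monotonicity is NON-strict: markers sharing one map position (a
recombination bin) all extend a run.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .map_model import MapCollection, Marker, ScaffoldConfiguration

__all__ = [
    "lms",
    "ScoreBreakdown",
    "score_configuration",
    "best_configuration_bruteforce",
]


def _longest_nondecreasing(values: Sequence[float]) -> int:
    # patience sorting; bisect_right realizes non-strict runs
    tails: list[float] = []
    for v in values:
        i = bisect_right(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def lms(values: Sequence[float]) -> int:
    """Longest monotonic subsequence length: max of the longest
    non-decreasing and longest non-increasing subsequences.  O(n log n).
    """
    if not values:
        return 0
    return max(
        _longest_nondecreasing(values),
        _longest_nondecreasing([-v for v in values]),
    )


@dataclass
class ScoreBreakdown:
    """Per-map LMS lengths and weights, plus the total L."""

    per_map: dict[str, tuple[int, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(n * w for n, w in self.per_map.values())


def _scaffold_track_positions(
    maps: MapCollection,
    track_members: Mapping[str, Iterable[str]] | None = None,
) -> dict[tuple[str, str], dict[str, list[float]]]:
    """map (map_name, lg) -> scaffold_id -> map positions sorted by pos."""
    out: dict[tuple[str, str], dict[str, list[tuple[int, float]]]] = {}
    for gm in maps.maps:
        allowed = None
        if track_members is not None:
            allowed = set(track_members.get(gm.name, gm.linkage_groups))
        for lg, markers in gm.linkage_groups.items():
            if allowed is not None and lg not in allowed:
                continue
            per_scaffold = out.setdefault((gm.name, lg), {})
            for m in markers:
                per_scaffold.setdefault(m.scaffold_id, []).append((m.pos, m.map_pos))
    result: dict[tuple[str, str], dict[str, list[float]]] = {}
    for track, per_scaffold in out.items():
        result[track] = {
            sid: [y for _, y in sorted(pairs)] for sid, pairs in per_scaffold.items()
        }
    return result


def score_configuration(
    config: ScaffoldConfiguration,
    maps: MapCollection,
    track_members: Mapping[str, Iterable[str]] | None = None,
) -> ScoreBreakdown:
    """Score a configuration against every map.

    ``track_members`` optionally restricts each map to a subset of its
    linkage groups (the cluster members of the chromosome being scored);
    by default all linkage groups contribute.  Orientation 0 scores as +1.
    Unknown scaffolds raise ``KeyError``.
    """
    known = {m.scaffold_id for m in maps}
    if maps.scaffold_sizes:
        known |= set(maps.scaffold_sizes)
    for sid, _ in config.entries:
        if sid not in known:
            raise KeyError(f"scaffold {sid!r} not present in the map collection")

    tracks = _scaffold_track_positions(maps, track_members)
    breakdown = ScoreBreakdown()
    weights = {gm.name: gm.weight for gm in maps.maps}
    for (map_name, _lg), per_scaffold in sorted(tracks.items()):
        seq: list[float] = []
        for sid, orient in config.entries:
            vals = per_scaffold.get(sid)
            if not vals:
                continue
            seq.extend(vals if orient >= 0 else vals[::-1])
        n, w = breakdown.per_map.get(map_name, (0, weights[map_name]))
        breakdown.per_map[map_name] = (n + lms(seq), w)
    for gm in maps.maps:
        breakdown.per_map.setdefault(gm.name, (0, gm.weight))
    return breakdown


def best_configuration_bruteforce(
    scaffold_ids: Sequence[str],
    maps: MapCollection,
    chromosome_id: str = "chr",
    track_members: Mapping[str, Iterable[str]] | None = None,
) -> ScaffoldConfiguration:
    """Exhaustive search over all orders and signs; test oracle only.

    Ties are broken by lexicographic order of (permutation of input
    indices, sign vector with +1 sorting before -1).  Limited to 8
    scaffolds.
    """
    n = len(scaffold_ids)
    if n > 8:
        raise ValueError("brute force limited to <= 8 scaffolds")
    if n == 0:
        return ScaffoldConfiguration(chromosome_id, [])
    # precompute per-track, per-scaffold map position tuples once
    tracks = _scaffold_track_positions(maps, track_members)
    weights = {gm.name: gm.weight for gm in maps.maps}
    fwd: list[tuple[float, list[tuple], list[tuple]]] = []
    for (map_name, _lg), per_scaffold in sorted(tracks.items()):
        f = [tuple(per_scaffold.get(sid, ())) for sid in scaffold_ids]
        fwd.append((weights[map_name], f, [ys[::-1] for ys in f]))
    best: tuple[float, tuple, tuple] | None = None
    # signs encoded 0 -> +1, 1 -> -1 so lexicographic iteration order matches
    # the documented tie-break
    for perm in itertools.permutations(range(n)):
        for bits in itertools.product((0, 1), repeat=n):
            score = 0.0
            for w, f, r in fwd:
                seq: list[float] = []
                for i, b in zip(perm, bits):
                    seq.extend(f[i] if b == 0 else r[i])
                score += w * lms(seq)
            if best is None or score > best[0]:
                best = (score, perm, bits)
    assert best is not None
    _, perm, bits = best
    return ScaffoldConfiguration(
        chromosome_id,
        [(scaffold_ids[i], 1 if b == 0 else -1) for i, b in zip(perm, bits)],
    )
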