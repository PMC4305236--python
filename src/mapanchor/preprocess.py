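"""Partition the anchoring problem by chromosome.

Steps: choose the pivot map (largest weight, input order breaking ties),
cluster homologous linkage groups around the pivot's linkage groups,
assign each scaffold to its best cluster by weighted marker counts
(flagging chimeric ties), and drop markers with erratic map positions
using the modified z-score (median/MAD) outlier test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .map_model import MapCollection, Marker

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageCluster",
    "ChromosomeProblem",
    "PreprocessReport",
    "select_pivot",
    "cluster_linkage_groups",
    "assign_scaffolds",
    "remove_outlier_markers",
    "preprocess",
]

#: modified z-score constant and cutoff for the median/MAD outlier test
MODIFIED_Z_CONSTANT = 0.6745
MODIFIED_Z_CUTOFF = 3.5


@dataclass
class LinkageCluster:
    """A cluster of homologous linkage groups seeded by one pivot group."""

    chromosome_id: str
    members: list[tuple[str, str]] = field(default_factory=list)
    scaffolds: set[str] = field(default_factory=set)
    skipped_chimeric: set[str] = field(default_factory=set)

    def member_lgs(self, map_name: str) -> set[str]:
        return {lg for m, lg in self.members if m == map_name}


@dataclass
class ChromosomeProblem:
    """One chromosome's optimization sub-problem, post-filtering.

    ``tracks`` maps (map_name, linkage_group) to a per-scaffold dict of
    markers (sorted by physical position).  ``scaffold_ids`` is in input
    appearance order — the deterministic tie-break everywhere downstream.
    """

    chromosome_id: str
    scaffold_ids: list[str]
    tracks: dict[tuple[str, str], dict[str, list[Marker]]]
    weights: dict[str, float]
    pivot: str
    scaffold_sizes: dict[str, int] = field(default_factory=dict)

    def track_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for map_name, lg in self.tracks:
            out.setdefault(map_name, set()).add(lg)
        return out

    def markers_on(self, scaffold_id: str) -> list[Marker]:
        found = []
        for per_scaffold in self.tracks.values():
            found.extend(per_scaffold.get(scaffold_id, []))
        return found

    @property
    def n_markers(self) -> int:
        return sum(
            len(v) for per_scaffold in self.tracks.values() for v in per_scaffold.values()
        )


@dataclass
class PreprocessReport:
    pivot: str = ""
    clusters: list[LinkageCluster] = field(default_factory=list)
    unassigned_groups: list[tuple[str, str]] = field(default_factory=list)
    chimeric_scaffolds: set[str] = field(default_factory=set)
    removed_outliers: list[Marker] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"pivot map: {self.pivot}"]
        for c in self.clusters:
            members = ", ".join(f"{m}-{lg}" for m, lg in c.members)
            lines.append(
                f"cluster {c.chromosome_id}: members [{members}] "
                f"scaffolds {len(c.scaffolds)}"
            )
        if self.unassigned_groups:
            groups = ", ".join(f"{m}-{lg}" for m, lg in self.unassigned_groups)
            lines.append(f"unassigned linkage groups: {groups}")
        if self.chimeric_scaffolds:
            lines.append(
                "chimeric scaffolds skipped: " + ", ".join(sorted(self.chimeric_scaffolds))
            )
        lines.append(f"outlier markers removed: {len(self.removed_outliers)}")
        return "\n".join(lines)


def select_pivot(maps: MapCollection) -> str:
    """The pivot map: maximal weight, first in input order on ties."""
    if not maps.maps:
        raise ValueError("empty map collection: no pivot map")
    best = maps.maps[0]
    for gm in maps.maps[1:]:
        if gm.weight > best.weight:
            best = gm
    return best.name


def _lg_scaffolds(maps: MapCollection, map_name: str, lg: str) -> set[str]:
    return {m.scaffold_id for m in maps.get_map(map_name).linkage_groups[lg]}


def cluster_linkage_groups(maps: MapCollection) -> tuple[list[LinkageCluster], list[tuple[str, str]]]:
    """Cluster homologous linkage groups around the pivot map's groups.

    Every non-pivot linkage group joins the cluster whose pivot seed
    shares the most scaffolds with it (ties to the earlier cluster);
    groups sharing no scaffolds with any cluster are left unassigned.
    Returns (clusters, unassigned (map, lg) pairs).
    """
    pivot = select_pivot(maps)
    clusters = [
        LinkageCluster(chromosome_id=lg, members=[(pivot, lg)])
        for lg in maps.get_map(pivot).linkage_groups
    ]
    seeds = [_lg_scaffolds(maps, pivot, lg) for lg in maps.get_map(pivot).linkage_groups]
    unassigned: list[tuple[str, str]] = []
    for gm in maps.maps:
        if gm.name == pivot:
            continue
        for lg in gm.linkage_groups:
            scaffolds = _lg_scaffolds(maps, gm.name, lg)
            shared = [len(scaffolds & seed) for seed in seeds]
            best = max(shared, default=0)
            if best == 0:
                logger.warning(
                    "linkage group %s-%s shares no scaffolds with any cluster; "
                    "left unassigned",
                    gm.name,
                    lg,
                )
                unassigned.append((gm.name, lg))
                continue
            clusters[shared.index(best)].members.append((gm.name, lg))
    return clusters, unassigned


def assign_scaffolds(
    clusters: Sequence[LinkageCluster], maps: MapCollection
) -> set[str]:
    """Assign each scaffold to the cluster with the largest weighted
    marker count; exact ties are chimeric and skipped with an alert.

    Mutates ``clusters`` in place and returns the chimeric scaffold set.
    """
    weights = {gm.name: gm.weight for gm in maps.maps}
    member_index: dict[tuple[str, str], int] = {}
    for ci, cluster in enumerate(clusters):
        for member in cluster.members:
            member_index[member] = ci

    counts: dict[str, dict[int, float]] = {}
    for marker in maps:
        ci = member_index.get(marker.track)
        if ci is None:
            continue
        per_cluster = counts.setdefault(marker.scaffold_id, {})
        per_cluster[ci] = per_cluster.get(ci, 0.0) + weights[marker.map_name]

    chimeric: set[str] = set()
    for sid, per_cluster in counts.items():
        best = max(per_cluster.values())
        winners = sorted(ci for ci, v in per_cluster.items() if v == best)
        if len(winners) > 1:
            chimeric.add(sid)
            clusters[winners[0]].skipped_chimeric.add(sid)
            logger.warning(
                "chimeric scaffold %s maps equally well to clusters %s; skipped",
                sid,
                ", ".join(clusters[ci].chromosome_id for ci in winners),
            )
            continue
        clusters[winners[0]].scaffolds.add(sid)
    return chimeric


def remove_outlier_markers(
    markers: Sequence[Marker],
    cutoff: float = MODIFIED_Z_CUTOFF,
    constant: float = MODIFIED_Z_CONSTANT,
) -> tuple[list[Marker], list[Marker]]:
    """Drop markers whose map position is erratic for one
    (scaffold, map, linkage group) marker set.

    Uses the modified z-score z = constant * (y - median) / MAD; markers
    with |z| > cutoff are removed.  Degenerate cases (fewer than 3
    markers, or MAD == 0) remove nothing.  Returns (kept, removed).
    """
    if len(markers) < 3:
        return list(markers), []
    ys = sorted(m.map_pos for m in markers)
    mid = len(ys) // 2
    median = ys[mid] if len(ys) % 2 else (ys[mid - 1] + ys[mid]) / 2.0
    devs = sorted(abs(y - median) for y in ys)
    mad = devs[mid] if len(devs) % 2 else (devs[mid - 1] + devs[mid]) / 2.0
    if mad == 0:
        return list(markers), []
    kept, removed = [], []
    for m in markers:
        z = constant * (m.map_pos - median) / mad
        (removed if abs(z) > cutoff else kept).append(m)
    return kept, removed


def preprocess(
    maps: MapCollection,
    outlier_cutoff: float = MODIFIED_Z_CUTOFF,
) -> tuple[list[ChromosomeProblem], PreprocessReport]:
    """Full preprocessing: cluster, assign, filter.

    Returns one :class:`ChromosomeProblem` per pivot linkage group (in
    pivot map order) plus a report of clusters, chimera alerts and
    removed outliers.
    """
    report = PreprocessReport(pivot=select_pivot(maps))
    clusters, unassigned = cluster_linkage_groups(maps)
    report.clusters = clusters
    report.unassigned_groups = unassigned
    report.chimeric_scaffolds = assign_scaffolds(clusters, maps)

    appearance: dict[str, int] = {}
    for i, sid in enumerate(maps.scaffolds_with_markers()):
        appearance[sid] = i

    weights = {gm.name: gm.weight for gm in maps.maps}
    problems: list[ChromosomeProblem] = []
    for cluster in clusters:
        members = set(cluster.members)
        tracks: dict[tuple[str, str], dict[str, list[Marker]]] = {}
        for gm in maps.maps:
            for lg, markers in gm.linkage_groups.items():
                if (gm.name, lg) not in members:
                    continue
                per_scaffold: dict[str, list[Marker]] = {}
                for m in markers:
                    if m.scaffold_id in cluster.scaffolds:
                        per_scaffold.setdefault(m.scaffold_id, []).append(m)
                filtered: dict[str, list[Marker]] = {}
                for sid, ms in per_scaffold.items():
                    kept, removed = remove_outlier_markers(ms, cutoff=outlier_cutoff)
                    report.removed_outliers.extend(removed)
                    if kept:
                        filtered[sid] = sorted(kept, key=lambda m: m.pos)
                if filtered:
                    tracks[(gm.name, lg)] = filtered
        sids = {sid for per_scaffold in tracks.values() for sid in per_scaffold}
        problems.append(
            ChromosomeProblem(
                chromosome_id=cluster.chromosome_id,
                scaffold_ids=sorted(sids, key=appearance.__getitem__),
                tracks=tracks,
                weights=weights,
                pivot=report.pivot,
                scaffold_sizes=maps.scaffold_sizes,
            )
        )
    return problems, report
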