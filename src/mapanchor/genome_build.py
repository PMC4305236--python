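"""Realize optimized scaffold configurations as genome releases.

Outputs are pseudomolecule FASTA (scaffolds concatenated with N gaps,
reverse-complemented where needed), AGP v2.0 rows (gap rows as
``U / scaffold / yes / map``), UCSC CHAIN records for coordinate liftOver,
a tab-separated build summary, and an optional spline-based per-junction
gap size estimate.
"""

from __future__ import annotations

import datetime
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .map_model import MapCollection, ScaffoldConfiguration
from .preprocess import ChromosomeProblem

logger = logging.getLogger(__name__)

__all__ = [
    "AGPRow",
    "ChainRecord",
    "BuildSummary",
    "GenomeBuild",
    "build_genome",
    "estimate_gaps",
    "write_consensus_map",
    "reverse_complement",
]

DEFAULT_GAP = 100
_COMPLEMENT = str.maketrans(
    "ACGTUacgtuNnRYSWKMBDHVryswkmbdhv", "TGCAAtgcaaNnYRSWMKVHDByrswmkvhdb"
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AGPRow:
    """One AGP v2.0 row; component rows (W) or gap rows (U)."""

    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # "W" or "U"
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"

    def to_line(self) -> str:
        if self.component_type == "U":
            tail = [str(self.gap_length), self.gap_type, self.linkage, self.evidence]
        else:
            tail = [
                self.component_id,
                str(self.component_beg),
                str(self.component_end),
                self.orientation,
            ]
        return "\t".join(
            [
                self.object,
                str(self.object_beg),
                str(self.object_end),
                str(self.part_number),
                self.component_type,
                *tail,
            ]
        )


@dataclass
class ChainRecord:
    """A single-block UCSC chain mapping one scaffold onto a chromosome.

    Coordinates are 0-based half-open; for a '-' strand query the start
    and end are expressed on the reverse-complemented query sequence, per
    the chain spec.
    """

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    chain_id: int

    def to_lines(self) -> str:
        # full-length single block: start/end are 0..size on either strand
        q_start, q_end = 0, self.q_size
        header = (
            f"chain {self.score} {self.t_name} {self.t_size} + "
            f"{self.t_start} {self.t_end} {self.q_name} {self.q_size} "
            f"{self.q_strand} {q_start} {q_end} {self.chain_id}"
        )
        return f"{header}\n{self.t_end - self.t_start}\n"


@dataclass
class Placement:
    scaffold_id: str
    chrom: str
    start: int  # 0-based
    length: int
    orientation: int  # +1 / -1 / 0 (0 written as '?', sequence forward)


@dataclass
class BuildSummary:
    """Per-map / anchored / unplaced statistics table."""

    columns: list[str] = field(default_factory=list)
    rows: dict[str, dict[str, object]] = field(default_factory=dict)

    ROW_ORDER = [
        "Linkage groups",
        "Markers (unique)",
        "Markers per Mb",
        "N50 scaffolds",
        "Scaffolds",
        "Scaffolds with 1 marker",
        "Scaffolds with 2 markers",
        "Scaffolds with 3 markers",
        "Scaffolds with >=4 markers",
        "Total bases",
        "Percent of genome",
    ]

    def to_tsv(self) -> str:
        lines = ["\t".join(["Statistic", *self.columns])]
        for row_name in self.ROW_ORDER:
            values = [
                str(self.rows.get(col, {}).get(row_name, "n.a.")) for col in self.columns
            ]
            lines.append("\t".join([row_name, *values]))
        return "\n".join(lines) + "\n"


@dataclass
class GenomeBuild:
    placements: dict[str, Placement]
    chrom_lengths: dict[str, int]
    agp_rows: list[AGPRow]
    chains: list[ChainRecord]
    summary: BuildSummary
    fasta_path: Path | None = None

    def lift(self, scaffold_id: str, pos: int) -> tuple[str, int, str]:
        """Map a 0-based scaffold position to (chromosome, position, strand)."""
        p = self.placements[scaffold_id]
        if not 0 <= pos < p.length:
            raise ValueError(f"position {pos} outside scaffold {scaffold_id}")
        if p.orientation < 0:
            return p.chrom, p.start + (p.length - 1 - pos), "-"
        return p.chrom, p.start + pos, "+"


def _assembly_n50(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    acc = 0
    for v in sorted(lengths, reverse=True):
        acc += v
        if acc * 2 >= total:
            return v
    return 0


def _summary_column(
    scaffolds: Sequence[str],
    sizes: Mapping[str, int],
    marker_counts: Mapping[str, int],
    n50_len: int,
    genome_total: int,
    n_linkage_groups: object,
    n_unique_markers: int,
) -> dict[str, object]:
    total = sum(sizes[s] for s in scaffolds)
    bins = {1: 0, 2: 0, 3: 0, 4: 0}
    for s in scaffolds:
        c = marker_counts.get(s, 0)
        if c >= 4:
            bins[4] += 1
        elif c > 0:
            bins[c] += 1
    mb = total / 1e6
    return {
        "Linkage groups": n_linkage_groups,
        "Markers (unique)": n_unique_markers,
        "Markers per Mb": round(n_unique_markers / mb, 1) if mb else 0.0,
        "N50 scaffolds": sum(1 for s in scaffolds if sizes[s] >= n50_len),
        "Scaffolds": len(scaffolds),
        "Scaffolds with 1 marker": bins[1],
        "Scaffolds with 2 markers": bins[2],
        "Scaffolds with 3 markers": bins[3],
        "Scaffolds with >=4 markers": bins[4],
        "Total bases": total,
        "Percent of genome": (
            f"{100.0 * total / genome_total:.1f}%" if genome_total else "0.0%"
        ),
    }


def _build_summary(
    placements: Mapping[str, Placement],
    sizes: Mapping[str, int],
    collection: MapCollection | None,
    n_chromosomes: int,
) -> BuildSummary:
    summary = BuildSummary()
    anchored = [s for s in sizes if s in placements]
    unplaced = [s for s in sizes if s not in placements]
    genome_total = sum(sizes.values())
    n50_len = _assembly_n50(list(sizes.values()))

    columns: list[str] = []
    if collection is not None:
        for gm in collection.maps:
            columns.append(gm.name)
    columns += ["Anchored", "Unplaced"]
    summary.columns = columns

    all_unique: dict[str, set[tuple[str, int]]] = {"anchored": set(), "unplaced": set()}
    union_counts: dict[str, set[tuple[str, int]]] = {}
    if collection is not None:
        for gm in collection.maps:
            per_scaffold: dict[str, set[tuple[str, int]]] = {}
            for m in gm:
                per_scaffold.setdefault(m.scaffold_id, set()).add((m.scaffold_id, m.pos))
                union_counts.setdefault(m.scaffold_id, set()).add((m.scaffold_id, m.pos))
                key = "anchored" if m.scaffold_id in placements else "unplaced"
                all_unique[key].add((m.scaffold_id, m.pos))
            covered = [s for s in anchored if s in per_scaffold]
            counts = {s: len(v) for s, v in per_scaffold.items()}
            summary.rows[gm.name] = _summary_column(
                covered,
                sizes,
                counts,
                n50_len,
                genome_total,
                len(gm.linkage_groups),
                sum(len(per_scaffold.get(s, ())) for s in covered),
            )

    union = {s: len(v) for s, v in union_counts.items()}
    summary.rows["Anchored"] = _summary_column(
        anchored, sizes, union, n50_len, genome_total,
        n_chromosomes, len(all_unique["anchored"]),
    )
    summary.rows["Unplaced"] = _summary_column(
        unplaced, sizes, union, n50_len, genome_total,
        "n.a.", len(all_unique["unplaced"]),
    )
    return summary


def build_genome(
    configs: Sequence[ScaffoldConfiguration],
    fasta_path: str | os.PathLike,
    out_prefix: str | os.PathLike,
    gap_size: int = DEFAULT_GAP,
    gap_sizes: Mapping[str, Sequence[int]] | None = None,
    collection: MapCollection | None = None,
    metadata: Mapping[str, object] | None = None,
) -> GenomeBuild:
    """Write pseudomolecule FASTA, AGP, CHAIN and summary files.

    ``gap_sizes`` optionally supplies per-junction gap lengths keyed by
    chromosome id (see :func:`estimate_gaps`); otherwise every junction
    gets ``gap_size`` Ns.  Unanchored scaffolds are carried through the
    FASTA unchanged and appear as single-row AGP objects.
    """
    from pyfaidx import Fasta

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = Fasta(str(fasta_path))
    sizes = {name: len(rec) for name, rec in fasta.items()}

    placements: dict[str, Placement] = {}
    chrom_lengths: dict[str, int] = {}
    agp_rows: list[AGPRow] = []
    chains: list[ChainRecord] = []
    chain_id = 0
    chrom_seqs: list[tuple[str, list[str]]] = []

    for config in configs:
        if not config.entries:
            continue
        chrom = config.chromosome_id
        pieces: list[str] = []
        cursor = 0  # 0-based
        part = 0
        junction_gaps = gap_sizes.get(chrom) if gap_sizes else None
        for k, (sid, orient) in enumerate(config.entries):
            if sid not in sizes:
                raise KeyError(f"scaffold {sid!r} missing from FASTA")
            if sid in placements:
                raise ValueError(f"scaffold {sid!r} placed more than once")
            if k > 0:
                gap = int(junction_gaps[k - 1]) if junction_gaps else gap_size
                part += 1
                agp_rows.append(
                    AGPRow(chrom, cursor + 1, cursor + gap, part, "U", gap_length=gap)
                )
                pieces.append("N" * gap)
                cursor += gap
            length = sizes[sid]
            seq = str(fasta[sid][:])
            if orient < 0:
                seq = reverse_complement(seq)
            pieces.append(seq)
            part += 1
            agp_rows.append(
                AGPRow(
                    chrom,
                    cursor + 1,
                    cursor + length,
                    part,
                    "W",
                    component_id=sid,
                    component_beg=1,
                    component_end=length,
                    orientation={1: "+", -1: "-", 0: "?"}[orient],
                )
            )
            placements[sid] = Placement(sid, chrom, cursor, length, orient)
            cursor += length
        chrom_lengths[chrom] = cursor
        chrom_seqs.append((chrom, pieces))

    # chains need final chromosome sizes
    for config in configs:
        for sid, orient in config.entries:
            p = placements[sid]
            chain_id += 1
            chains.append(
                ChainRecord(
                    score=p.length,
                    t_name=p.chrom,
                    t_size=chrom_lengths[p.chrom],
                    t_start=p.start,
                    t_end=p.start + p.length,
                    q_name=sid,
                    q_size=p.length,
                    q_strand="-" if orient < 0 else "+",
                    chain_id=chain_id,
                )
            )

    for sid, length in sizes.items():
        if sid not in placements:
            agp_rows.append(
                AGPRow(
                    sid, 1, length, 1, "W",
                    component_id=sid, component_beg=1, component_end=length,
                    orientation="+",
                )
            )

    summary = _build_summary(placements, sizes, collection, len(chrom_lengths))

    fasta_out = out_prefix.with_suffix(".fasta")
    with open(fasta_out, "w") as fh:
        for chrom, pieces in chrom_seqs:
            _write_fasta_record(fh, chrom, "".join(pieces))
        for sid in sizes:
            if sid not in placements:
                _write_fasta_record(fh, sid, str(fasta[sid][:]))

    with open(out_prefix.with_suffix(".agp"), "w") as fh:
        fh.write(f"# generated by mapanchor on {datetime.date.today().isoformat()}\n")
        fh.write(f"# source assembly: {fasta_path}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        for row in agp_rows:
            fh.write(row.to_line() + "\n")

    with open(out_prefix.with_suffix(".chain"), "w") as fh:
        for chain in chains:
            fh.write(chain.to_lines() + "\n")

    with open(out_prefix.with_suffix(".summary.tsv"), "w") as fh:
        fh.write(summary.to_tsv())

    fasta.close()
    return GenomeBuild(
        placements=placements,
        chrom_lengths=chrom_lengths,
        agp_rows=agp_rows,
        chains=chains,
        summary=summary,
        fasta_path=fasta_out,
    )


def _write_fasta_record(fh, name: str, seq: str, width: int = 60) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")
    if not seq:
        fh.write("\n")


# ---------------------------------------------------------------------------
# Gap size estimation
# ---------------------------------------------------------------------------


def estimate_gaps(
    config: ScaffoldConfiguration,
    problem: ChromosomeProblem,
    default_gap: int = DEFAULT_GAP,
    min_gap: int = 10,
    max_gap: int = 1_000_000,
) -> list[int]:
    """Per-junction gap sizes from spline-interpolated recombination rates.

    A provisional chromosome is laid out with ``default_gap`` spacing; for
    every map track with >= 4 distinct marker positions a cubic spline of
    map position against provisional physical position supplies a local
    rate (its derivative at the junction midpoint).  Every flanking marker
    pair converts its map-distance to physical distance at that rate minus
    the two scaffold overhangs; the junction gap is the smallest estimate
    over all pairs and maps, clamped to [min_gap, max_gap].  Junctions with
    no usable flanking markers keep ``default_gap``.
    """
    from scipy.interpolate import CubicSpline

    sizes = problem.scaffold_sizes
    entries = config.entries
    if len(entries) < 2:
        return []
    starts: dict[str, int] = {}
    cursor = 0
    for sid, _ in entries:
        starts[sid] = cursor
        cursor += sizes[sid] + default_gap

    def lifted(sid: str, pos: int, orient: int) -> int:
        if orient < 0:
            return starts[sid] + sizes[sid] - 1 - pos
        return starts[sid] + pos

    # per track: markers lifted onto provisional coordinates, plus spline
    track_points: dict[tuple[str, str], dict[str, list[tuple[int, float]]]] = {}
    splines: dict[tuple[str, str], object] = {}
    orient_of = dict(entries)
    for track, per_scaffold in problem.tracks.items():
        pts: dict[str, list[tuple[int, float]]] = {}
        for sid, markers in per_scaffold.items():
            if sid not in starts:
                continue
            pts[sid] = [
                (lifted(sid, m.pos, orient_of[sid]), m.map_pos) for m in markers
            ]
        if not pts:
            continue
        track_points[track] = pts
        flat = sorted(p for sid_pts in pts.values() for p in sid_pts)
        xs: list[float] = []
        ys: list[float] = []
        for x, y in flat:
            if xs and x == xs[-1]:
                ys[-1] = (ys[-1] + y) / 2.0
            else:
                xs.append(x)
                ys.append(y)
        if len(xs) >= 4:
            splines[track] = CubicSpline(xs, ys)

    gaps: list[int] = []
    for k in range(len(entries) - 1):
        left_sid, _ = entries[k]
        right_sid, _ = entries[k + 1]
        left_end = starts[left_sid] + sizes[left_sid]  # exclusive
        right_start = starts[right_sid]
        mid = (left_end + right_start) / 2.0
        best: float | None = None
        for track, spline in splines.items():
            pts = track_points[track]
            lpts = pts.get(left_sid)
            rpts = pts.get(right_sid)
            if not lpts or not rpts:
                continue
            rate = abs(float(spline(mid, 1)))
            if rate <= 0 or not np.isfinite(rate):
                continue
            for x1, y1 in lpts:
                over_left = left_end - 1 - x1
                for x2, y2 in rpts:
                    over_right = x2 - right_start
                    est = abs(y2 - y1) / rate - over_left - over_right
                    if best is None or est < best:
                        best = est
        if best is None:
            logger.warning(
                "%s: junction %s|%s has no usable flanking markers; "
                "keeping default gap %d",
                config.chromosome_id, left_sid, right_sid, default_gap,
            )
            gaps.append(default_gap)
        else:
            gaps.append(int(min(max(best, min_gap), max_gap)))
    return gaps


def write_consensus_map(
    build: GenomeBuild,
    collection: MapCollection,
    path: str | os.PathLike,
) -> None:
    """Re-express every placed marker in chromosome coordinates, sorted.

    Columns: chromosome, lifted position (0-based), map, linkage group,
    original map position, scaffold, scaffold position.
    """
    rows = []
    for marker in collection:
        if marker.scaffold_id not in build.placements:
            continue
        chrom, pos, _strand = build.lift(marker.scaffold_id, marker.pos)
        rows.append(
            (
                chrom,
                pos,
                marker.map_name,
                marker.linkage_group,
                marker.map_pos,
                marker.scaffold_id,
                marker.pos,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tmap\tlinkage_group\tmap_position\tscaffold\tscaffold_position\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
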