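"""Domain types and I/O for marker maps.

The central abstraction is a *marker*: a single observation linking a
physical position on an assembly scaffold (bp) to a position on a named
genomic map (cM for genetic maps, scaled bp for optical or synteny maps).
Markers are exchanged in a 4-column BED dialect::

    scaffold_1   100    101    JMMale-1:31.6

where column 4 encodes ``<map>-<linkage_group>:<map_position>``.  Map
positions are parsed as plain floats with no unit enforcement; any linear
rescaling of a map's positions leaves the optimization unchanged.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "GenomicMap",
    "MapCollection",
    "ScaffoldConfiguration",
    "MarkerBedError",
    "parse_marker_bed",
    "write_marker_bed",
    "parse_weights",
    "merge_csv_maps",
    "read_scaffold_sizes",
]


class MarkerBedError(ValueError):
    """Raised for malformed marker BED or weights input."""


@dataclass(frozen=True)
class Marker:
    """One observation tying a scaffold position to a map position.

    ``pos`` is a 0-based point position on the scaffold, taken as the
    midpoint of the originating BED interval.
    """

    scaffold_id: str
    pos: int
    map_name: str
    linkage_group: str
    map_pos: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative marker position: {self.pos}")
        if not (self.map_name and self.linkage_group):
            raise ValueError("map name and linkage group must be non-empty")
        if self.map_pos != self.map_pos or self.map_pos in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite map position: {self.map_pos}")

    @property
    def track(self) -> tuple[str, str]:
        """(map_name, linkage_group) pair identifying the scoring track."""
        return (self.map_name, self.linkage_group)


@dataclass
class GenomicMap:
    """A named map with a weight and markers grouped by linkage group."""

    name: str
    weight: float = 1.0
    linkage_groups: dict[str, list[Marker]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"map weight must be positive, got {self.weight}")

    def add(self, marker: Marker) -> None:
        self.linkage_groups.setdefault(marker.linkage_group, []).append(marker)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.linkage_groups.values())

    def __iter__(self) -> Iterator[Marker]:
        for markers in self.linkage_groups.values():
            yield from markers


@dataclass
class MapCollection:
    """All input maps plus scaffold metadata.

    ``maps`` preserves user input order — the tie-break for pivot-map
    selection.  ``scaffold_sizes`` may be empty until a FASTA is attached.
    """

    maps: list[GenomicMap] = field(default_factory=list)
    scaffold_sizes: dict[str, int] = field(default_factory=dict)

    def get_map(self, name: str) -> GenomicMap:
        for m in self.maps:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def map_names(self) -> list[str]:
        return [m.name for m in self.maps]

    def add_marker(self, marker: Marker) -> None:
        for m in self.maps:
            if m.name == marker.map_name:
                m.add(marker)
                return
        gm = GenomicMap(marker.map_name)
        gm.add(marker)
        self.maps.append(gm)

    def __iter__(self) -> Iterator[Marker]:
        for m in self.maps:
            yield from m

    @property
    def n_markers(self) -> int:
        return sum(m.n_markers for m in self.maps)

    def scaffolds_with_markers(self) -> list[str]:
        """Scaffold ids carrying at least one marker, in first-seen order."""
        seen: dict[str, None] = {}
        for marker in self:
            seen.setdefault(marker.scaffold_id, None)
        return list(seen)

    def apply_weights(self, weights: Mapping[str, float]) -> None:
        """Assign per-map weights; unknown names warn, absent maps keep 1."""
        known = set(self.map_names)
        for name in weights:
            if name not in known:
                logger.warning("weights file names unknown map %r", name)
        for m in self.maps:
            m.weight = float(weights.get(m.name, 1.0))
            if m.weight <= 0:
                raise MarkerBedError(f"non-positive weight for map {m.name}")

    def validate(self) -> None:
        """Check markers against scaffold sizes (if sizes are attached)."""
        if not self.scaffold_sizes:
            return
        for marker in self:
            size = self.scaffold_sizes.get(marker.scaffold_id)
            if size is None:
                raise MarkerBedError(
                    f"marker scaffold {marker.scaffold_id!r} absent from assembly"
                )
            if marker.pos >= size:
                raise MarkerBedError(
                    f"marker at {marker.scaffold_id}:{marker.pos} exceeds "
                    f"scaffold length {size}"
                )


@dataclass
class ScaffoldConfiguration:
    """An ordered, signed scaffold sequence for one chromosome.

    Orientation is +1 (forward), -1 (reverse) or 0 (undetermined; scored
    as forward, written as '?' in AGP output).
    """

    chromosome_id: str
    entries: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scaffold in configuration")
        for _, o in self.entries:
            if o not in (-1, 0, 1):
                raise ValueError(f"invalid orientation {o}")

    @property
    def scaffold_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def reversed_(self) -> "ScaffoldConfiguration":
        """Global flip: reverse order and negate every non-zero sign."""
        return ScaffoldConfiguration(
            self.chromosome_id, [(sid, -o) for sid, o in reversed(self.entries)]
        )


def _parse_label(label: str) -> tuple[str, str, float]:
    head, sep, pos = label.rpartition(":")
    if not sep:
        raise ValueError("missing ':' separator")
    map_name, sep, lg = head.rpartition("-")
    if not sep or not map_name or not lg:
        raise ValueError("missing '-' separator between map and linkage group")
    return map_name, lg, float(pos)


def parse_marker_bed(path: str | os.PathLike) -> MapCollection:
    """Parse the 4-column marker BED dialect into a :class:`MapCollection`.

    Intervals are 0-based half-open; the marker point position is the
    interval midpoint.  Exact duplicate rows are dropped once with a
    warning; rows differing in any field are kept as distinct markers.
    Raises :class:`MarkerBedError` naming the offending line number.
    """
    collection = MapCollection()
    seen_rows: set[tuple] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MarkerBedError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            scaffold, start_s, end_s, label = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise MarkerBedError(
                    f"{path}:{lineno}: non-integer interval {start_s!r}..{end_s!r}"
                ) from None
            if start >= end:
                raise MarkerBedError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            try:
                map_name, lg, map_pos = _parse_label(label)
            except ValueError as exc:
                raise MarkerBedError(
                    f"{path}:{lineno}: malformed marker label {label!r} ({exc})"
                ) from None
            key = (scaffold, start, end, map_name, lg, map_pos)
            if key in seen_rows:
                logger.warning("%s:%d: duplicate row dropped", path, lineno)
                continue
            seen_rows.add(key)
            collection.add_marker(
                Marker(scaffold, (start + end) // 2, map_name, lg, map_pos)
            )
    return collection


def write_marker_bed(collection: MapCollection, path: str | os.PathLike) -> None:
    """Write markers back out in the BED dialect (1-bp intervals)."""
    with open(path, "w") as fh:
        for marker in collection:
            fh.write(
                f"{marker.scaffold_id}\t{marker.pos}\t{marker.pos + 1}\t"
                f"{marker.map_name}-{marker.linkage_group}:{marker.map_pos:g}\n"
            )


def parse_weights(path: str | os.PathLike | None) -> dict[str, float]:
    """Parse a whitespace-separated ``name weight`` file.

    A missing file yields an empty mapping (all maps then default to
    weight 1).  Non-positive or non-numeric weights raise.
    """
    weights: dict[str, float] = {}
    if path is None or not Path(path).exists():
        if path is not None:
            logger.warning("weights file %s not found; all maps weight 1", path)
        return weights
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise MarkerBedError(
                    f"{path}:{lineno}: expected 'name weight', got {line!r}"
                )
            name, weight_s = parts
            try:
                weight = float(weight_s)
            except ValueError:
                raise MarkerBedError(
                    f"{path}:{lineno}: non-numeric weight {weight_s!r}"
                ) from None
            if weight <= 0:
                raise MarkerBedError(f"{path}:{lineno}: weight must be positive")
            weights[name] = weight
    return weights


def merge_csv_maps(
    csv_paths: Sequence[str | os.PathLike], out_path: str | os.PathLike
) -> Path:
    """Convert per-map CSV files into one marker BED file.

    Each CSV row is ``scaffold_id,pos,linkage_group,map_pos``; the map name
    is the CSV file's stem.  Emitted intervals are ``pos .. pos+1``, so the
    output round-trips losslessly through :func:`parse_marker_bed`.
    """
    out_path = Path(out_path)
    with open(out_path, "w") as out:
        for csv_path in csv_paths:
            map_name = Path(csv_path).stem
            with open(csv_path, newline="") as fh:
                for lineno, row in enumerate(csv.reader(fh), 1):
                    if not row:
                        continue
                    if len(row) != 4:
                        raise MarkerBedError(
                            f"{csv_path}:{lineno}: expected 4 columns, got {len(row)}"
                        )
                    scaffold, pos_s, lg, map_pos = (f.strip() for f in row)
                    pos = int(pos_s)
                    out.write(
                        f"{scaffold}\t{pos}\t{pos + 1}\t"
                        f"{map_name}-{lg}:{float(map_pos):g}\n"
                    )
    return out_path


def read_scaffold_sizes(fasta_path: str | os.PathLike) -> dict[str, int]:
    """Scaffold lengths from an (indexed) FASTA."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fasta:
        return {name: len(rec) for name, rec in fasta.items()}
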