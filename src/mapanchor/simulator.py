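"""Synthetic-data generator and evaluation harness.

Simulates a Medicago-like genome (8 chromosomes, 366 Mb by default) cut
into scaffolds with a log-normal length profile, places markers uniformly,
derives per-map marker subsets at a constant cM/bp rate, and injects
controlled inversion and translocation errors.  Reconstruction quality is
scored as LMS-over-total-markers colinearity against the simulated truth.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .colinearity import lms
from .map_model import GenomicMap, MapCollection, Marker, ScaffoldConfiguration

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "TrueMarker",
    "ErrorModel",
    "SimulatedMaps",
    "default_chromosome_lengths",
    "simulate_assembly",
    "simulate_maps",
    "accuracy",
    "write_random_fasta",
]

GENOME_TOTAL = 366_000_000
N_CHROMOSOMES = 8

# log-normal scaffold length profile fitted to the reference preliminary
# assembly summary: 20,591 sequences, N50 46 kb, largest 346 kb.  Mean
# length fixes mu given sigma; sigma comes from the N50/mean ratio (the
# N50 is the median of the length-biased distribution, exp(mu + sigma^2)).
_PROFILE_COUNT = 20_591
_PROFILE_N50 = 46_000
_PROFILE_MAX = 346_000
_PROFILE_MEAN = GENOME_TOTAL / _PROFILE_COUNT
PROFILE_SIGMA = math.sqrt(2.0 * math.log(_PROFILE_N50 / _PROFILE_MEAN))
PROFILE_MU = math.log(_PROFILE_MEAN) - PROFILE_SIGMA**2 / 2.0

DEFAULT_CM_PER_MB = 2.0


@dataclass(frozen=True)
class TrueMarker:
    marker_id: int
    chrom: str
    chrom_pos: int
    scaffold_id: str
    scaffold_pos: int


@dataclass
class SimulationTruth:
    """Ground truth: chromosome sizes, scaffold placements, markers."""

    chrom_lengths: dict[str, int]
    placements: dict[str, tuple[str, int, int, int]]  # sid -> (chrom, start, length, orient)
    markers: list[TrueMarker] = field(default_factory=list)

    def scaffold_sizes(self) -> dict[str, int]:
        return {sid: length for sid, (_, _, length, _) in self.placements.items()}

    def write_tsv(self, out_dir: str | os.PathLike) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "truth_scaffolds.tsv", "w") as fh:
            fh.write("scaffold\tchromosome\tstart\tlength\torientation\n")
            for sid, (chrom, start, length, orient) in self.placements.items():
                fh.write(f"{sid}\t{chrom}\t{start}\t{length}\t{orient:+d}\n")
        with open(out_dir / "truth_markers.tsv", "w") as fh:
            fh.write("marker_id\tchromosome\tposition\tscaffold\tscaffold_position\n")
            for m in self.markers:
                fh.write(
                    f"{m.marker_id}\t{m.chrom}\t{m.chrom_pos}\t"
                    f"{m.scaffold_id}\t{m.scaffold_pos}\n"
                )


@dataclass(frozen=True)
class ErrorModel:
    """Map corruption levels.

    ``p_inv``: fraction of a chromosome's markers inside implanted
    inversions (0.5 is the most extreme case).  ``p_trans``: fraction
    translocated, split 75% intra- / 25% inter-chromosomal; the
    inter-chromosomal moves corrupt the linkage-group label.
    """

    p_inv: float = 0.0
    p_trans: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inv <= 0.5:
            raise ValueError(f"p_inv out of range [0, 0.5]: {self.p_inv}")
        if not 0.0 <= self.p_trans <= 1.0:
            raise ValueError(f"p_trans out of range [0, 1]: {self.p_trans}")


def default_chromosome_lengths(
    total: int = GENOME_TOTAL, n_chromosomes: int = N_CHROMOSOMES
) -> dict[str, int]:
    base = total // n_chromosomes
    lengths = {f"chr{i + 1}": base for i in range(n_chromosomes)}
    lengths[f"chr{n_chromosomes}"] += total - base * n_chromosomes
    return lengths


def simulate_assembly(
    chrom_lengths: dict[str, int] | None = None,
    n_scaffolds: int | None = None,
    seed: int = 0,
    length_profile: tuple[float, float] | None = None,
    max_length: int = _PROFILE_MAX,
) -> SimulationTruth:
    """Cut chromosomes into scaffolds with log-normal lengths and random
    true orientations.

    ``n_scaffolds`` rescales the length profile so the expected scaffold
    count over the whole genome matches (the last scaffold of each
    chromosome is truncated at the chromosome end).  Deterministic under
    ``seed``.
    """
    chrom_lengths = chrom_lengths or default_chromosome_lengths()
    total = sum(chrom_lengths.values())
    if total <= 0:
        raise ValueError("empty genome")
    mu, sigma = length_profile or (PROFILE_MU, PROFILE_SIGMA)
    scale = 1.0
    if n_scaffolds is not None:
        if n_scaffolds < len(chrom_lengths):
            raise ValueError("need at least one scaffold per chromosome")
        target_mean = total / n_scaffolds
        profile_mean = math.exp(mu + sigma**2 / 2.0)
        scale = target_mean / profile_mean
    rng = np.random.default_rng(seed)
    placements: dict[str, tuple[str, int, int, int]] = {}
    counter = 0
    for chrom, clen in chrom_lengths.items():
        cursor = 0
        while cursor < clen:
            length = int(min(rng.lognormal(mu, sigma) * scale, max_length * scale))
            length = max(length, 200)
            length = min(length, clen - cursor)
            orient = 1 if rng.random() < 0.5 else -1
            counter += 1
            placements[f"scf_{counter:06d}"] = (chrom, cursor, length, orient)
            cursor += length
    return SimulationTruth(chrom_lengths=dict(chrom_lengths), placements=placements)


@dataclass
class SimulatedMaps:
    """Per-map marker observations plus the emitted error bookkeeping."""

    truth: SimulationTruth
    # map name -> list of (marker_id, scaffold_id, scaffold_pos, lg, map_pos)
    maps: dict[str, list[tuple[int, str, int, str, float]]]

    def observed_marker_ids(self) -> set[int]:
        return {mid for recs in self.maps.values() for mid, *_ in recs}

    def to_collection(self, weights: dict[str, float] | None = None) -> MapCollection:
        collection = MapCollection(scaffold_sizes=self.truth.scaffold_sizes())
        for name, records in self.maps.items():
            gm = GenomicMap(name, weight=(weights or {}).get(name, 1.0))
            for mid, sid, spos, lg, mpos in records:
                gm.add(Marker(sid, spos, name, lg, mpos))
            collection.maps.append(gm)
        return collection

    def write_beds(self, out_dir: str | os.PathLike) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, records in self.maps.items():
            path = out_dir / f"{name}.bed"
            with open(path, "w") as fh:
                for mid, sid, spos, lg, mpos in sorted(records, key=lambda r: (r[1], r[2])):
                    fh.write(f"{sid}\t{spos}\t{spos + 1}\t{name}-{lg}:{mpos:.6f}\n")
            paths.append(path)
        return paths


def _pick_run(rng: np.random.Generator, n: int, mean_len: int) -> range:
    start = int(rng.integers(0, n))
    length = 1 + int(rng.geometric(1.0 / mean_len))
    return range(start, min(start + length, n))


def simulate_maps(
    truth: SimulationTruth,
    n_markers: int,
    n_maps: int = 1,
    keep_fraction: float = 2.0 / 3.0,
    error: ErrorModel | None = None,
    corrupt: Sequence[int] | None = None,
    seed: int = 0,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    inversion_run: int = 10,
    translocation_run: int = 5,
) -> SimulatedMaps:
    """Place ``n_markers`` uniformly, subset them into ``n_maps`` maps and
    inject errors.

    Each map receives each marker independently with probability
    ``keep_fraction``.  ``corrupt`` lists the map indices subjected to the
    error model (default: all maps when an error model is given).  Fills
    ``truth.markers`` as a side effect.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction out of range (0, 1]: {keep_fraction}")
    error = error or ErrorModel()
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    clens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    total = clens.sum()

    # uniform genome-wide positions -> (chrom, pos), sorted
    raw = np.sort(rng.uniform(0, total, size=n_markers))
    bounds = np.cumsum(clens)
    idx = np.searchsorted(bounds, raw, side="right")
    offsets = np.concatenate([[0.0], bounds[:-1]])

    # scaffold lookup per chromosome
    per_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in chroms:
        items = [
            (start, sid)
            for sid, (c, start, _, _) in truth.placements.items()
            if c == chrom
        ]
        items.sort()
        per_chrom[chrom] = (np.array([s for s, _ in items]), [sid for _, sid in items])

    truth.markers = []
    for mid, (ci, g) in enumerate(zip(idx, raw)):
        chrom = chroms[ci]
        pos = int(g - offsets[ci])
        pos = min(pos, truth.chrom_lengths[chrom] - 1)
        starts, sids = per_chrom[chrom]
        si = int(np.searchsorted(starts, pos, side="right")) - 1
        sid = sids[si]
        _, start, length, orient = truth.placements[sid]
        within = pos - start
        spos = within if orient > 0 else length - 1 - within
        truth.markers.append(TrueMarker(mid, chrom, pos, sid, spos))

    if corrupt is None:
        corrupt = list(range(n_maps)) if (error.p_inv or error.p_trans) else []
    corrupt_set = set(corrupt)

    maps: dict[str, list[tuple[int, str, int, str, float]]] = {}
    for mi in range(n_maps):
        name = f"Map{mi + 1}"
        keep = rng.random(n_markers) < keep_fraction
        # per chromosome, markers in true order with provisional map_pos
        by_chrom: dict[str, list[list]] = {c: [] for c in chroms}
        for m in truth.markers:
            if not keep[m.marker_id]:
                continue
            by_chrom[m.chrom].append(
                [m.marker_id, m.scaffold_id, m.scaffold_pos, m.chrom,
                 m.chrom_pos * cm_per_mb / 1e6]
            )
        if mi in corrupt_set:
            _inject_errors(by_chrom, truth, error, rng, cm_per_mb,
                           inversion_run, translocation_run)
        records = [tuple(rec) for recs in by_chrom.values() for rec in recs]
        maps[name] = records
    return SimulatedMaps(truth=truth, maps=maps)


def _inject_errors(
    by_chrom: dict[str, list[list]],
    truth: SimulationTruth,
    error: ErrorModel,
    rng: np.random.Generator,
    cm_per_mb: float,
    inversion_run: int,
    translocation_run: int,
) -> None:
    chroms = list(by_chrom)
    spans = {c: truth.chrom_lengths[c] * cm_per_mb / 1e6 for c in chroms}
    for chrom in chroms:
        recs = by_chrom[chrom]
        n = len(recs)
        if n < 2:
            continue
        # inversions: reverse map positions of contiguous runs until the
        # marker budget is met
        involved: set[int] = set()
        budget = error.p_inv * n
        guard = 0
        while len(involved) < budget and guard < 10 * n:
            guard += 1
            run = _pick_run(rng, n, inversion_run)
            if len(run) < 2:
                continue
            ys = [recs[i][4] for i in run]
            for i, y in zip(run, reversed(ys)):
                recs[i][4] = y
            involved.update(run)
        # translocations: relocate runs; 75% intra-, 25% inter-chromosomal
        moved = 0
        budget = error.p_trans * n
        guard = 0
        while moved < budget and guard < 10 * n:
            guard += 1
            run = _pick_run(rng, n, translocation_run)
            if not len(run):
                continue
            base_y = recs[run[0]][4]
            if rng.random() < 0.75 or len(chroms) == 1:
                new_base = float(rng.uniform(0, spans[chrom]))
                for i in run:
                    recs[i][4] = new_base + (recs[i][4] - base_y)
            else:
                others = [c for c in chroms if c != chrom]
                target = others[int(rng.integers(0, len(others)))]
                new_base = float(rng.uniform(0, spans[target]))
                for i in run:
                    recs[i][3] = target
                    recs[i][4] = new_base + (recs[i][4] - base_y)
            moved += len(run)


def accuracy(
    configs: Iterable[ScaffoldConfiguration],
    truth: SimulationTruth,
    observed_marker_ids: set[int] | None = None,
) -> float:
    """LMS-over-total-markers colinearity between a reconstruction and
    the truth.

    Per reconstructed chromosome, truth markers are taken in the order
    implied by the reconstruction and the LMS of their true positions is
    computed over the markers belonging to the chromosome's majority truth
    chromosome; markers on unplaced or mis-clustered scaffolds count only
    in the denominator.  1.0 means perfect colinearity.
    """
    markers = truth.markers
    if observed_marker_ids is not None:
        markers = [m for m in markers if m.marker_id in observed_marker_ids]
    if not markers:
        return 1.0
    by_scaffold: dict[str, list[TrueMarker]] = {}
    for m in markers:
        by_scaffold.setdefault(m.scaffold_id, []).append(m)
    for ms in by_scaffold.values():
        ms.sort(key=lambda m: m.scaffold_pos)

    numerator = 0
    for config in configs:
        ordered: list[TrueMarker] = []
        for sid, orient in config.entries:
            ms = by_scaffold.get(sid, [])
            ordered.extend(ms if orient >= 0 else ms[::-1])
        if not ordered:
            continue
        counts: dict[str, int] = {}
        for m in ordered:
            counts[m.chrom] = counts.get(m.chrom, 0) + 1
        majority = max(sorted(counts), key=counts.__getitem__)
        seq = [float(m.chrom_pos) for m in ordered if m.chrom == majority]
        numerator += lms(seq)
    return numerator / len(markers)


def write_random_fasta(
    truth: SimulationTruth, path: str | os.PathLike, seed: int = 0, width: int = 60
) -> Path:
    """Random A/C/G/T sequence for every scaffold, for build testing."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    path = Path(path)
    with open(path, "w") as fh:
        for sid, (_, _, length, _) in truth.placements.items():
            seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode()
            fh.write(f">{sid}\n")
            for i in range(0, length, width):
                fh.write(seq[i : i + width] + "\n")
    return path
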