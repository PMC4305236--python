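from collections import defaultdict

import numpy as np
import pytest

from mapanchor.genome_build import (
    AGPRow,
    build_genome,
    estimate_gaps,
    reverse_complement,
    write_consensus_map,
)
from mapanchor.map_model import Marker, ScaffoldConfiguration
from mapanchor.preprocess import ChromosomeProblem

from .conftest import make_collection


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


@pytest.fixture
def small_assembly(tmp_path):
    rng = np.random.default_rng(0)
    records = {
        "s1": "".join(rng.choice(list("ACGT"), size=10)),
        "s2": "".join(rng.choice(list("ACGT"), size=20)),
        "s3": "".join(rng.choice(list("ACGT"), size=15)),
    }
    fasta = tmp_path / "asm.fasta"
    write_fasta(fasta, records)
    return fasta, records


class TestBuildGenome:
    def test_agp_arithmetic(self, small_assembly, tmp_path):
        fasta, records = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", -1)])
        build = build_genome([config], fasta, tmp_path / "out", gap_size=100)
        assert build.chrom_lengths["chr1"] == 130
        rows = [r for r in build.agp_rows if r.object == "chr1"]
        assert [(r.object_beg, r.object_end, r.component_type) for r in rows] == [
            (1, 10, "W"),
            (11, 110, "U"),
            (111, 130, "W"),
        ]
        assert rows[0].orientation == "+"
        assert rows[1].gap_length == 100
        assert rows[1].gap_type == "scaffold"
        assert rows[1].linkage == "yes"
        assert rows[1].evidence == "map"
        assert rows[2].orientation == "-"

    def test_unknown_orientation_written_as_question_mark(
        self, small_assembly, tmp_path
    ):
        fasta, _ = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 0)])
        build = build_genome([config], fasta, tmp_path / "out")
        [row] = [r for r in build.agp_rows if r.object == "chr1"]
        assert row.orientation == "?"

    def test_reverse_complement_applied(self, small_assembly, tmp_path):
        fasta, records = small_assembly
        config = ScaffoldConfiguration("chr1", [("s2", -1)])
        build = build_genome([config], fasta, tmp_path / "out")
        from pyfaidx import Fasta

        out = Fasta(str(build.fasta_path))
        assert str(out["chr1"][:]) == reverse_complement(records["s2"])

    def test_unplaced_carried_through(self, small_assembly, tmp_path):
        fasta, records = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 1)])
        build = build_genome([config], fasta, tmp_path / "out")
        from pyfaidx import Fasta

        out = Fasta(str(build.fasta_path))
        assert str(out["s2"][:]) == records["s2"]
        unplaced_rows = [r for r in build.agp_rows if r.object == "s2"]
        assert len(unplaced_rows) == 1
        assert unplaced_rows[0].component_type == "W"

    def test_missing_scaffold_raises(self, small_assembly, tmp_path):
        fasta, _ = small_assembly
        config = ScaffoldConfiguration("chr1", [("nope", 1)])
        with pytest.raises(KeyError):
            build_genome([config], fasta, tmp_path / "out")

    def test_duplicate_placement_raises(self, small_assembly, tmp_path):
        fasta, _ = small_assembly
        configs = [
            ScaffoldConfiguration("chr1", [("s1", 1)]),
            ScaffoldConfiguration("chr2", [("s1", 1)]),
        ]
        with pytest.raises(ValueError):
            build_genome(configs, fasta, tmp_path / "out")

    def test_agp_rows_tile_chromosome(self, small_assembly, tmp_path):
        fasta, _ = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", -1), ("s3", 1)])
        build = build_genome([config], fasta, tmp_path / "out", gap_size=7)
        spans = sorted(
            (r.object_beg, r.object_end)
            for r in build.agp_rows
            if r.object == "chr1"
        )
        assert spans[0][0] == 1
        assert spans[-1][1] == build.chrom_lengths["chr1"]
        for (_, end), (beg, _) in zip(spans, spans[1:]):
            assert beg == end + 1

    def test_liftover_roundtrip(self, small_assembly, tmp_path):
        fasta, records = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", -1), ("s3", 0)])
        build = build_genome([config], fasta, tmp_path / "out")
        from pyfaidx import Fasta

        out = Fasta(str(build.fasta_path))
        comp = str.maketrans("ACGT", "TGCA")
        for sid, seq in records.items():
            for pos in range(len(seq)):
                chrom, cpos, strand = build.lift(sid, pos)
                base = str(out[chrom][cpos])
                if strand == "-":
                    base = base.translate(comp)
                assert base == seq[pos], (sid, pos)

    def test_chain_records(self, small_assembly, tmp_path):
        fasta, _ = small_assembly
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", -1)])
        build = build_genome([config], fasta, tmp_path / "out")
        by_query = {c.q_name: c for c in build.chains}
        assert by_query["s1"].q_strand == "+"
        assert by_query["s2"].q_strand == "-"
        c = by_query["s2"]
        assert c.t_end - c.t_start == c.q_size  # one full-length block
        lines = c.to_lines().splitlines()
        assert lines[0].startswith("chain ")
        assert lines[1] == str(c.q_size)

    def test_summary_totals(self, small_assembly, tmp_path):
        fasta, records = small_assembly
        collection = make_collection(
            [("s1", 2, "M", "1", 0.5), ("s2", 3, "M", "1", 1.5)],
            sizes={k: len(v) for k, v in records.items()},
        )
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", 1)])
        build = build_genome([config], fasta, tmp_path / "out", collection=collection)
        anchored = build.summary.rows["Anchored"]
        unplaced = build.summary.rows["Unplaced"]
        total = sum(len(v) for v in records.values())
        assert anchored["Total bases"] + unplaced["Total bases"] == total
        assert anchored["Scaffolds"] == 2
        assert unplaced["Scaffolds"] == 1
        assert anchored["Markers (unique)"] == 2


class TestEstimateGaps:
    def _linear_problem(self, sizes, markers, chromosome="chr1"):
        tracks = {}
        for m in markers:
            tracks.setdefault((m.map_name, m.linkage_group), {}).setdefault(
                m.scaffold_id, []
            ).append(m)
        for per in tracks.values():
            for ms in per.values():
                ms.sort(key=lambda m: m.pos)
        return ChromosomeProblem(
            chromosome_id=chromosome,
            scaffold_ids=list(sizes),
            tracks=tracks,
            weights={"M": 1.0},
            pivot="M",
            scaffold_sizes=sizes,
        )

    def test_linear_rate_arithmetic(self):
        # map positions exactly linear at 1 cM/Mb in chromosome coordinates
        # with a true 50 kb gap: flanking markers ~0.1 cM apart with
        # overhangs 20 kb + 30 kb -> gap = 100,000 - 50,000 = 50,000 bp
        sizes = {"L": 100_000, "R": 100_000}
        rate = 1e-6  # cM per bp
        true_gap = 50_000

        def l_marker(pos):
            return Marker("L", pos, "M", "1", pos * rate)

        def r_marker(pos):
            return Marker("R", pos, "M", "1", (100_000 + true_gap + pos) * rate)

        markers = [
            l_marker(10_000),
            l_marker(50_000),
            l_marker(100_000 - 1 - 20_000),  # overhang 20 kb
            r_marker(30_000),  # overhang 30 kb
            r_marker(60_000),
            r_marker(90_000),
        ]
        problem = self._linear_problem(sizes, markers)
        config = ScaffoldConfiguration("chr1", [("L", 1), ("R", 1)])
        # lay the provisional build out at the true gap so the fitted
        # spline is exactly linear; the estimate then reproduces the
        # hand-computed arithmetic to within a base
        [gap] = estimate_gaps(config, problem, default_gap=true_gap)
        assert abs(gap - true_gap) <= 1

    def test_negative_estimate_clamped_to_min(self):
        sizes = {"L": 100_000, "R": 100_000}
        # markers nearly identical in map position but huge overhangs
        markers = [
            Marker("L", 0, "M", "1", 0.0),
            Marker("L", 10_000, "M", "1", 0.01),
            Marker("R", 90_000, "M", "1", 0.02),
            Marker("R", 99_000, "M", "1", 0.03),
        ]
        problem = self._linear_problem(sizes, markers)
        config = ScaffoldConfiguration("chr1", [("L", 1), ("R", 1)])
        [gap] = estimate_gaps(config, problem, min_gap=10)
        assert gap == 10

    def test_smallest_estimate_wins_across_maps(self):
        sizes = {"L": 1_000_000, "R": 1_000_000}
        markers = []
        # map A: 1 cM/Mb; flanking pair 0.04 cM apart, no overhang -> 40 kb
        for x, y in [(0, 0.0), (400_000, 0.4), (999_999, 1.0)]:
            markers.append(Marker("L", x, "A", "1", y))
        for x, y in [(0, 1.04), (500_000, 1.54), (999_999, 2.04)]:
            markers.append(Marker("R", x, "A", "1", y))
        # map B: 2 cM/Mb; flanking pair 0.05 cM apart -> 25 kb
        for x, y in [(0, 0.0), (400_000, 0.8), (999_999, 2.0)]:
            markers.append(Marker("L", x, "B", "1", y))
        for x, y in [(0, 2.05), (500_000, 3.05), (999_999, 4.05)]:
            markers.append(Marker("R", x, "B", "1", y))
        tracks = {}
        for m in markers:
            tracks.setdefault((m.map_name, m.linkage_group), {}).setdefault(
                m.scaffold_id, []
            ).append(m)
        for per in tracks.values():
            for ms in per.values():
                ms.sort(key=lambda m: m.pos)
        problem = ChromosomeProblem(
            "chr1", list(sizes), tracks, {"A": 1.0, "B": 1.0}, "A", sizes
        )
        config = ScaffoldConfiguration("chr1", [("L", 1), ("R", 1)])
        [gap] = estimate_gaps(config, problem)
        assert gap < 40_000  # map B's smaller estimate wins

    def test_no_flanking_markers_keeps_default(self):
        sizes = {"L": 1000, "R": 1000}
        problem = ChromosomeProblem("chr1", list(sizes), {}, {"M": 1.0}, "M", sizes)
        config = ScaffoldConfiguration("chr1", [("L", 1), ("R", 1)])
        assert estimate_gaps(config, problem, default_gap=100) == [100]

    def test_single_scaffold_no_junctions(self):
        sizes = {"L": 1000}
        problem = ChromosomeProblem("chr1", ["L"], {}, {"M": 1.0}, "M", sizes)
        config = ScaffoldConfiguration("chr1", [("L", 1)])
        assert estimate_gaps(config, problem) == []


class TestConsensusMap:
    def test_lifted_positions_sorted_and_reverse_arithmetic(
        self, small_assembly, tmp_path
    ):
        fasta, records = small_assembly
        collection = make_collection(
            [
                ("s1", 2, "M", "1", 0.5),
                ("s2", 3, "M", "1", 1.5),
                ("s2", 15, "M", "1", 1.2),
                ("s3", 0, "M", "1", 9.0),  # unplaced
            ],
            sizes={k: len(v) for k, v in records.items()},
        )
        config = ScaffoldConfiguration("chr1", [("s1", 1), ("s2", -1)])
        build = build_genome([config], fasta, tmp_path / "out", collection=collection)
        out = tmp_path / "consensus.tsv"
        write_consensus_map(build, collection, out)
        lines = out.read_text().splitlines()[1:]
        positions = [int(line.split("\t")[1]) for line in lines]
        assert positions == sorted(positions)
        assert len(lines) == 3  # unplaced marker excluded
        # marker on the - scaffold: start + (len - 1 - pos)
        s2_start = build.placements["s2"].start
        expected = s2_start + (20 - 1 - 3)
        assert any(int(l.split("\t")[1]) == expected for l in lines)


class TestAGPRow:
    def test_component_line(self):
        row = AGPRow("chr1", 1, 10, 1, "W", "s1", 1, 10, "+")
        assert row.to_line() == "chr1\t1\t10\t1\tW\ts1\t1\t10\t+"

    def test_gap_line(self):
        row = AGPRow("chr1", 11, 110, 2, "U", gap_length=100)
        assert row.to_line() == "chr1\t11\t110\t2\tU\t100\tscaffold\tyes\tmap"


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement(reverse_complement("ACGTTTGA")) == "ACGTTTGA"
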