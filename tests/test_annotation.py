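"""Tests for gene-free region construction and exon shifting."""

import pytest

from xbseq.annotation import (
    GeneModel,
    Interval,
    build_gene_free_regions,
    read_background_gtf,
    shift_annotation,
    shift_gene,
    write_background_gtf,
)
from xbseq.fixtures import make_fixture
from xbseq.annotation import (
    read_chrom_sizes,
    read_gene_models_gtf,
    read_intervals_bed,
)


def iv(chrom, s, e, strand="."):
    return Interval(chrom, s, e, strand)


class TestGeneFreeRegions:
    def test_worked_interval_arithmetic(self):
        regions = build_gene_free_regions(
            {"chr1": 10_000},
            [iv("chr1", 1000, 2000), iv("chr1", 5000, 6000)],
            [iv("chr1", 1000, 6000)],
        )
        assert [(r.start, r.end) for r in regions] == [(2100, 4900), (7000, 9000)]

    def test_no_exclusions_whole_chromosome_trimmed(self):
        regions = build_gene_free_regions({"chr1": 10_000, "chr2": 4_000}, [], [])
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr1", 1000, 9000),
            ("chr2", 1000, 3000),
        ]

    def test_tiling_exclusions_leave_nothing(self):
        regions = build_gene_free_regions(
            {"chr1": 3000}, [iv("chr1", 0, 1500), iv("chr1", 1400, 3000)], []
        )
        assert regions == []

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError):
            build_gene_free_regions({"chr1": 1000}, [iv("chr1", 500, 2000)], [])
        with pytest.raises(ValueError):
            build_gene_free_regions({"chr1": 1000}, [iv("chrX", 0, 10)], [])


def _gene(gid="g", chrom="chr1", strand="+", exons=((100, 150), (180, 200))):
    return GeneModel(
        gid, chrom, strand, tuple(Interval(chrom, s, e, strand) for s, e in exons)
    )


class TestShiftGene:
    def test_structure_preserving_right_shift(self):
        shifted = shift_gene(_gene(), [iv("chr1", 300, 600)])
        assert [(e.start, e.end) for e in shifted.exons] == [(300, 350), (380, 400)]
        assert shifted.gene_id == "g" and shifted.strand == "+"

    def test_flush_fit_in_exact_length_region(self):
        shifted = shift_gene(_gene(), [iv("chr1", 300, 400)])  # span length 100
        assert [(e.start, e.end) for e in shifted.exons] == [(300, 350), (380, 400)]

    def test_structure_fit_searched_in_priority_order(self):
        regions = [iv("chr1", 0, 90), iv("chr1", 220, 250), iv("chr1", 400, 600)]
        shifted = shift_gene(_gene(), regions)
        # nearest right (220,250) and nearest left (0,90) are both too short
        # for the whole span; the second right region hosts the structure
        assert shifted.exons[0].start == 400

    def test_compact_mode_preserves_exon_sizes_only(self):
        g = _gene()
        needed = g.total_exon_length + len(g.exons) - 1  # 71
        shifted = shift_gene(g, [iv("chr1", 300, 300 + needed)])
        assert [(e.start, e.end) for e in shifted.exons] == [(300, 350), (351, 371)]
        assert shifted.total_exon_length == g.total_exon_length
        assert shifted.span_length != g.span_length

    def test_unplaceable_returns_marker(self):
        assert shift_gene(_gene(), [iv("chr1", 300, 330)]) is None
        assert shift_gene(_gene(), [iv("chr2", 300, 900)]) is None


class TestGtfRoundTrip:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "bg.gtf"
        write_background_gtf([_gene(exons=((300, 350),))], path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[2] == "exon" and fields[3] == "301" and fields[4] == "350"

    def test_empty_annotation_is_valid(self, tmp_path):
        path = tmp_path / "empty.gtf"
        write_background_gtf([], path)
        assert read_background_gtf(path) == []
        assert path.read_text().startswith("#")

    def test_round_trip_is_lossless(self, tmp_path, rng):
        genes = []
        for k in range(20):
            start = int(rng.integers(0, 100_000))
            exons = []
            pos = start
            for _ in range(int(rng.integers(1, 6))):
                ln = int(rng.integers(50, 500))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(1, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_gene(f"g{k}", "chr1", strand, exons))
        path = tmp_path / "rt.gtf"
        write_background_gtf(genes, path)
        back = read_background_gtf(path)
        assert sorted(back, key=lambda g: g.gene_id) == sorted(
            genes, key=lambda g: g.gene_id
        )


class TestShiftAnnotationProperties:
    @pytest.fixture
    def toy(self, tmp_path):
        d = make_fixture("toy-genome", str(tmp_path / "toy"), seed=3)
        genes = read_gene_models_gtf(f"{d}/genes.gtf")
        sizes = read_chrom_sizes(f"{d}/chrom.sizes")
        extra = read_intervals_bed(f"{d}/exclude.bed")
        spans = [Interval(g.chrom, g.span[0], g.span[1]) for g in genes]
        exclusions = spans + extra
        regions = build_gene_free_regions(sizes, exclusions, spans)
        genes = sorted(genes, key=lambda g: (g.chrom, g.span[0]))
        return genes, exclusions, regions

    def test_invariants(self, toy):
        genes, exclusions, regions = toy
        placed, dropped = shift_annotation(genes, regions)
        assert len(placed) + len(dropped) == len(genes)
        assert placed, "toy genome should place at least some genes"
        by_id = {g.gene_id: g for g in genes}
        occupied = []
        for sg in placed:
            # exon length conserved per gene
            assert sg.total_exon_length == by_id[sg.gene_id].total_exon_length
            for e in sg.exons:
                for x in exclusions:
                    if x.chrom == e.chrom:
                        assert e.end <= x.start or e.start >= x.end, (
                            f"{sg.gene_id} overlaps exclusion {x}"
                        )
                for chrom, s, t in occupied:
                    if chrom == e.chrom:
                        assert e.end <= s or e.start >= t
            s, t = sg.span
            occupied.append((sg.chrom, s, t))

    def test_deterministic_given_order(self, toy):
        genes, _, regions = toy
        a, _ = shift_annotation(genes, regions)
        b, _ = shift_annotation(genes, regions)
        assert a == b
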