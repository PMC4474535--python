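"""Construction of the matched non-exonic ("shifted gene") annotation.

To measure per-gene sequencing background, each gene's exon structure is
relocated into gene-free genomic space of identical total exon length, so a
second counting pass over the shifted annotation yields an equivalent
non-exonic read count for every gene.  The pipeline:

1. take the complement of all transcript-evidence intervals per chromosome,
2. classify each gap as intronic (inside a gene span) or intergenic,
3. trim safety margins (100 bp intronic, 1000 bp intergenic by default),
4. place each gene's full exon-intron structure into the nearest fitting
   gene-free region (priority: nearest right, nearest left, next right, ...),
5. fall back to a compact placement preserving exon sizes only,
6. write the shifted models as a GTF.

Coordinates are 0-based half-open internally; GTF I/O converts to 1-based
inclusive at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "GeneModel",
    "build_gene_free_regions",
    "shift_gene",
    "shift_annotation",
    "write_background_gtf",
    "read_background_gtf",
    "read_gene_models_gtf",
    "read_gene_models_refflat",
    "read_intervals_bed",
    "read_intervals_gtf",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of non-overlapping exons on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        if any(e.chrom != self.chrom for e in exons):
            raise ValueError(f"gene {self.gene_id} has exons on several chromosomes")

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def total_exon_length(self) -> int:
        return sum(e.length for e in self.exons)


def _merge(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_gene_free_regions(
    chrom_sizes: Dict[str, int],
    exclusion_intervals: Sequence[Interval],
    gene_spans: Sequence[Interval],
    trim_intronic: int = 100,
    trim_intergenic: int = 1000,
) -> List[Interval]:
    """Gene-free regions: complement of the exclusion set, classified and
    trimmed.

    A gap fully contained in some gene span is intronic and trimmed by
    ``trim_intronic`` on each side; any other gap is intergenic and trimmed
    by ``trim_intergenic``.  Regions of non-positive length after trimming
    are dropped.
    """
    for iv in list(exclusion_intervals) + list(gene_spans):
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"chromosome {iv.chrom!r} missing from chrom sizes")
        if iv.end > size:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds length {size} of {iv.chrom}"
            )
    spans_by_chrom: Dict[str, IntervalTree] = {}
    for g in gene_spans:
        spans_by_chrom.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    excl_by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for iv in exclusion_intervals:
        excl_by_chrom[iv.chrom].append((iv.start, iv.end))

    regions: List[Interval] = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        merged = _merge(excl_by_chrom.get(chrom, []))
        gaps: List[Tuple[int, int]] = []
        cursor = 0
        for s, e in merged:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            gaps.append((cursor, size))
        tree = spans_by_chrom.get(chrom, IntervalTree())
        for s, e in gaps:
            intronic = any(g.begin <= s and e <= g.end for g in tree.overlap(s, e))
            trim = trim_intronic if intronic else trim_intergenic
            ts, te = s + trim, e - trim
            if ts < te:
                regions.append(Interval(chrom, ts, te))
    return regions


def shift_gene(gene: GeneModel, regions: Sequence[Interval]) -> Optional[GeneModel]:
    """Relocate a gene's exon structure into the first fitting gene-free
    region.

    Candidate regions on the gene's chromosome are visited in priority
    order: nearest to the right of the gene span, nearest to the left, next
    right, next left, and so on.  The first region long enough for the whole
    gene span hosts a structure-preserving copy at its left edge.  If none
    fits, a second pass places exons compactly (sizes preserved, 1-bp gaps).
    Returns ``None`` when the gene is unplaceable.
    """
    gs, ge = gene.span
    right = sorted(
        (r for r in regions if r.chrom == gene.chrom and r.start >= ge),
        key=lambda r: r.start,
    )
    left = sorted(
        (r for r in regions if r.chrom == gene.chrom and r.end <= gs),
        key=lambda r: -r.end,
    )
    candidates: List[Interval] = []
    for i in range(max(len(right), len(left))):
        if i < len(right):
            candidates.append(right[i])
        if i < len(left):
            candidates.append(left[i])

    for region in candidates:
        if region.length >= gene.span_length:
            offset = region.start - gs
            exons = tuple(
                Interval(gene.chrom, e.start + offset, e.end + offset, gene.strand)
                for e in gene.exons
            )
            return replace(gene, exons=exons)
    needed = gene.total_exon_length + (len(gene.exons) - 1)
    for region in candidates:
        if region.length >= needed:
            exons = []
            pos = region.start
            for e in gene.exons:
                exons.append(Interval(gene.chrom, pos, pos + e.length, gene.strand))
                pos += e.length + 1
            return replace(gene, exons=tuple(exons))
    return None


def _remove_span(
    regions: List[Interval], chrom: str, start: int, end: int
) -> List[Interval]:
    """Carve [start, end) out of the region list (occupancy update)."""
    out: List[Interval] = []
    for r in regions:
        if r.chrom != chrom or r.end <= start or r.start >= end:
            out.append(r)
            continue
        if r.start < start:
            out.append(Interval(r.chrom, r.start, start, r.strand))
        if end < r.end:
            out.append(Interval(r.chrom, end, r.end, r.strand))
    return out


def shift_annotation(
    genes: Sequence[GeneModel], regions: Sequence[Interval]
) -> Tuple[List[GeneModel], List[str]]:
    """Shift every gene, treating earlier placements as occupied space.

    Genes are processed in input order; each placed gene's full span is
    removed from the available regions so no two shifted genes overlap.
    Returns the placed models and the ids of unplaceable genes.
    """
    avail = list(regions)
    placed: List[GeneModel] = []
    dropped: List[str] = []
    for gene in genes:
        shifted = shift_gene(gene, avail)
        if shifted is None:
            logger.warning("gene %s could not be placed in any gene-free region",
                           gene.gene_id)
            dropped.append(gene.gene_id)
            continue
        s, e = shifted.span
        avail = _remove_span(avail, shifted.chrom, s, e)
        placed.append(shifted)
    return placed, dropped


def write_background_gtf(shifted: Sequence[GeneModel], path) -> None:
    """Write shifted models as GTF exon features (1-based inclusive)."""
    try:
        with open(path, "w") as fh:
            fh.write("## shifted non-exonic background annotation\n")
            for gene in shifted:
                for e in gene.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{gene.gene_id}"; '
                        f'original_gene_id "{gene.gene_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "xbseq",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
    except OSError as err:
        raise OSError(f"failed writing background GTF to {path}: {err}") from err


def _models_from_exon_features(features) -> List[GeneModel]:
    by_gene: Dict[str, dict] = {}
    for chrom, start, end, strand, gene_id in features:
        rec = by_gene.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "exons": []}
        )
        rec["exons"].append((start, end))
    models = []
    for gid, rec in by_gene.items():
        merged = _merge(rec["exons"])
        exons = tuple(
            Interval(rec["chrom"], s, e, rec["strand"]) for s, e in merged
        )
        models.append(GeneModel(gid, rec["chrom"], rec["strand"], exons))
    return models


def _iter_gtf_exons(path):
    from gffutils.feature import feature_from_line

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = feature_from_line(line)
            if f.featuretype != "exon":
                continue
            gid = f.attributes["gene_id"][0]
            yield f.seqid, f.start - 1, f.end, f.strand, gid


def read_background_gtf(path) -> List[GeneModel]:
    """Read back a shifted annotation written by :func:`write_background_gtf`."""
    return _models_from_exon_features(_iter_gtf_exons(path))


def read_gene_models_gtf(path) -> List[GeneModel]:
    """Gene models from a GTF: exon features unioned per gene_id."""
    return _models_from_exon_features(_iter_gtf_exons(path))


def read_gene_models_refflat(path) -> List[GeneModel]:
    """Gene models from a UCSC refFlat table (exon coordinates are already
    0-based half-open); transcripts of one gene are unioned."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            gene, _name, chrom, strand = parts[0], parts[1], parts[2], parts[3]
            starts = [int(x) for x in parts[9].rstrip(",").split(",")]
            ends = [int(x) for x in parts[10].rstrip(",").split(",")]
            for s, e in zip(starts, ends):
                feats.append((chrom, s, e, strand, gene))
    return _models_from_exon_features(feats)


def read_intervals_bed(path) -> List[Interval]:
    """Intervals from a BED file (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return out


def read_intervals_gtf(path) -> List[Interval]:
    """Intervals from any GTF feature lines (converted to half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append(Interval(parts[0], int(parts[3]) - 1, int(parts[4])))
    return out


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column chromosome sizes file."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
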