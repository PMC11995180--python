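"""Reference I/O: FASTA genomes, GTF gene models and a queryable index.

Internal coordinates are 0-based half-open throughout the package; GTF's
1-based closed convention is converted at the I/O boundary, in both
directions, so that a write/read round trip is exact.

Gene models are collapsed to gene level: exons of all transcripts are merged
into their interval union, because every downstream classification (exon
boundary vs. mid-exon breakpoints) is made per gene, not per isoform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import FormatError, ReferenceLookupError
from .seq import clean_sequence, revcomp

Interval = tuple[int, int]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: a name and an uppercase ACGTN sequence."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


class Genome(dict):
    """Mapping contig name -> GenomeSequence with checked access."""

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self:
            raise ReferenceLookupError(f"contig {contig!r} not in genome")
        return self[contig].seq[start:end]


@dataclass
class GeneModel:
    """A gene-level model: merged exons, optional 3'UTR, strand.

    ``exons`` are non-overlapping [start, end) intervals sorted by genomic
    coordinate.  ``utr3`` intervals, when present, lie within the exon span.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Interval]
    utr3: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not s < e:
                raise FormatError(f"gene {self.gene_id}: empty interval [{s},{e})")
        self.exons = merge_intervals(self.exons)
        span = self.span
        for s, e in self.utr3:
            if not (span[0] <= s < e <= span[1]):
                raise FormatError(
                    f"gene {self.gene_id}: utr3 [{s},{e}) outside exon span {span}"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def boundaries(self) -> frozenset[int]:
        return frozenset(x for iv in self.exons for x in iv)

    def contains(self, position: int) -> bool:
        s, e = self.span
        return s <= position < e

    def exonic(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def in_utr3(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.utr3)

    def effective_utr3(self) -> list[Interval] | None:
        """3'UTR intervals: annotated ones, else derived as the exonic region
        transcriptionally downstream of the CDS end; None if underivable."""
        if self.utr3:
            return self.utr3
        if not self.cds:
            return None
        if self.strand == "+":
            cut = max(e for _, e in self.cds)
            region = [(max(s, cut), e) for s, e in self.exons if e > cut]
        else:
            cut = min(s for s, _ in self.cds)
            region = [(s, min(e, cut)) for s, e in self.exons if s < cut]
        return [(s, e) for s, e in region if s < e]

    # -- spliced-transcript coordinate helpers -------------------------------
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: Genome) -> str:
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def transcript_offset(self, position: int) -> int:
        """0-based offset of exonic genomic *position* in the spliced transcript."""
        if not self.exonic(position):
            raise ValueError(f"position {position} not exonic in {self.gene_id}")
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if position < e:
                    return off + (position - s)
                off += e - s
        else:
            for s, e in reversed(self.exons):
                if position >= s:
                    return off + (e - 1 - position)
                off += e - s
        raise AssertionError("unreachable")


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of [start, end) intervals; touching intervals are merged."""
    merged: list[Interval] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class AnnotationIndex:
    """Gene models keyed by id plus a per-contig exon-span interval lookup."""

    def __init__(self, genes: dict[str, GeneModel] | list[GeneModel]):
        if not isinstance(genes, dict):
            genes = {g.gene_id: g for g in genes}
        self.genes: dict[str, GeneModel] = dict(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.contig, IntervalTree())
            tree.addi(g.span[0], g.span[1], g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise ReferenceLookupError(f"unknown gene id {gene_id!r}") from None

    def lookup(self, contig: str, position: int) -> set[str]:
        """Ids of genes whose exon span contains *position*."""
        tree = self._trees.get(contig)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(position)}

    def is_exon_boundary(self, gene_id: str, position: int, tolerance: int = 0) -> bool:
        """True iff *position* is (within *tolerance* of) an exon start or end.

        The caller passes the already-oriented half-open edge coordinate;
        donor edges compare against exon ends, acceptor edges against exon
        starts, but membership is tested against the union of both.
        """
        bounds = self.get(gene_id).boundaries
        if tolerance == 0:
            return position in bounds
        return any(abs(position - b) <= tolerance for b in bounds)

    def genes_on(self, contig: str) -> list[GeneModel]:
        out = [g for g in self.genes.values() if g.contig == contig]
        return sorted(out, key=lambda g: g.span)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a Genome, normalising to ACGTN upper."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genome = Genome()
    for rec in records:
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seq = clean_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} has empty sequence")
        genome[rec.id] = GenomeSequence(rec.id, seq)
    return genome


def write_genome(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, rec in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation(path: str | Path) -> AnnotationIndex:
    """Parse a GTF into an AnnotationIndex.

    Only ``exon`` and ``three_prime_utr`` features are used.  Exons of all
    transcripts of a gene are merged into their union.  1-based closed GTF
    coordinates become 0-based half-open.
    """
    path = Path(path)
    exons: dict[str, list[Interval]] = {}
    utrs: dict[str, list[Interval]] = {}
    cdss: dict[str, list[Interval]] = {}
    strands: dict[str, str] = {}
    contigs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _, feature, start_s, end_s, _, strand, _, attrs = fields
            if feature not in ("exon", "three_prime_utr", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            if gid in strands:
                if strands[gid] != strand:
                    raise FormatError(
                        f"{path}:{lineno}: gene {gid} has features on both strands"
                    )
                if contigs[gid] != contig:
                    raise FormatError(
                        f"{path}:{lineno}: gene {gid} spans multiple contigs"
                    )
            else:
                strands[gid], contigs[gid] = strand, contig
            iv = (start1 - 1, end1)  # to 0-based half-open
            bucket = {"exon": exons, "three_prime_utr": utrs, "CDS": cdss}[feature]
            bucket.setdefault(gid, []).append(iv)
    for gid in utrs:
        if gid not in exons:
            raise FormatError(f"{path}: gene {gid} has three_prime_utr but no exon features")
    if not exons:
        raise FormatError(f"{path}: no exon features found")
    genes = {
        gid: GeneModel(
            gene_id=gid,
            contig=contigs[gid],
            strand=strands[gid],
            exons=ivs,
            utr3=merge_intervals(utrs.get(gid, [])),
            cds=merge_intervals(cdss.get(gid, [])),
        )
        for gid, ivs in exons.items()
    }
    return AnnotationIndex(genes)


def write_annotation(index: AnnotationIndex, path: str | Path, source: str = "chimerakit") -> None:
    """Write an AnnotationIndex back to GTF (inverse of read_annotation)."""
    with open(path, "w") as fh:
        for gid in sorted(index.genes):
            g = index.genes[gid]
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.contig}\t{source}\tthree_prime_utr\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
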