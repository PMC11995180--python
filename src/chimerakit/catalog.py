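"""Fusion-candidate ingestion and junction-site / genomic classification.

Each candidate joins a 5' partner gene to a 3' partner gene at a pair of
genomic breakpoints and carries the transcript sequence around the junction.
Two independent labels are assigned:

* junction class -- E/E, E/M, M/E or M/M: per side, E iff the breakpoint
  lies on an annotated exon boundary of that gene (donor edge for the 5'
  side, acceptor edge for the 3' side, mirrored on the minus strand);
* genomic class -- inter-chromosomal (partners on different contigs),
  read-through (same strand, 5' gene transcriptionally upstream of the 3'
  gene, intergenic gap at most ``readthrough_max_gap``), or
  intra-chromosomal otherwise.

Breakpoints in candidate files are 1-based positions of the junction-adjacent
base (last transcribed base of the 5' segment, first of the 3' segment),
converted to the internal 0-based convention on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .annotation_io import AnnotationIndex
from .errors import ClassificationError, FormatError

log = logging.getLogger(__name__)

JUNCTION_CLASSES = ("E/E", "E/M", "M/E", "M/M")
GENOMIC_CLASSES = ("read-through", "intra-chromosomal", "inter-chromosomal")

#: Mandatory columns of the candidate TSV (breakpoints 1-based in files).
CANDIDATE_COLUMNS = [
    "sample_id",
    "gene_5p", "contig_5p", "strand_5p", "breakpoint_5p",
    "gene_3p", "contig_3p", "strand_3p", "breakpoint_3p",
    "junction_seq",
]


@dataclass(frozen=True)
class Partner:
    """One side of a chimera: gene, location and junction-adjacent base."""

    gene_id: str
    contig: str
    strand: str
    breakpoint: int  # 0-based position of the junction-adjacent base


@dataclass(frozen=True)
class ChimeraCandidate:
    """A single fusion call in one sample, optionally classified."""

    five: Partner
    three: Partner
    junction_seq: str
    sample_id: str
    score: float | None = None
    junction_class: str | None = None
    genomic_class: str | None = None

    @property
    def chimera_id(self) -> str:
        f, t = self.five, self.three
        return f"{f.gene_id}--{t.gene_id}@{f.breakpoint}:{t.breakpoint}"


def parse_candidates(
    path: str | Path, index: AnnotationIndex
) -> tuple[list[ChimeraCandidate], int]:
    """Read a candidate TSV; returns (candidates, dropped_row_count).

    Rows referencing genes absent from the annotation, or whose two partners
    are the same gene (self-fusion caller artifacts), are dropped and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    out: list[ChimeraCandidate] = []
    dropped = 0
    for row in df.itertuples(index=False):
        g5, g3 = row.gene_5p, row.gene_3p
        if g5 not in index or g3 not in index or g5 == g3:
            dropped += 1
            continue
        seq = str(row.junction_seq).upper()
        if len(seq) < 20:
            raise FormatError(f"{path}: junction sequence shorter than 20 nt for {g5}--{g3}")
        score = getattr(row, "score", None)
        out.append(
            ChimeraCandidate(
                five=Partner(g5, row.contig_5p, row.strand_5p, int(row.breakpoint_5p) - 1),
                three=Partner(g3, row.contig_3p, row.strand_3p, int(row.breakpoint_3p) - 1),
                junction_seq=seq,
                sample_id=row.sample_id,
                score=float(score) if score not in (None, "", "nan") else None,
            )
        )
    if dropped:
        log.info("%s: dropped %d row(s) with unknown or identical partner genes", path, dropped)
    return out, dropped


def _oriented_edge(position: int, strand: str, side: str) -> int:
    """Half-open edge coordinate of the junction for a breakpoint base.

    The donor (5') edge on '+' lies one past the last transcribed base; the
    acceptor (3') edge on '+' is the first transcribed base.  Minus-strand
    genes use the genomically mirrored edge.
    """
    if side == "5p":
        return position + 1 if strand == "+" else position
    return position if strand == "+" else position + 1


def classify_junction(
    cand: ChimeraCandidate, index: AnnotationIndex, tolerance: int = 0
) -> str:
    """Assign E/E, E/M, M/E or M/M from the two breakpoints."""
    labels = []
    for partner, side in ((cand.five, "5p"), (cand.three, "3p")):
        gene = index.get(partner.gene_id)
        if not gene.contains(partner.breakpoint):
            raise ClassificationError(
                f"{cand.chimera_id}: breakpoint {partner.breakpoint} outside span of {gene.gene_id}"
            )
        edge = _oriented_edge(partner.breakpoint, gene.strand, side)
        labels.append("E" if index.is_exon_boundary(gene.gene_id, edge, tolerance) else "M")
    return f"{labels[0]}/{labels[1]}"


def classify_genomic(
    cand: ChimeraCandidate, index: AnnotationIndex, readthrough_max_gap: int = 100_000
) -> str:
    """Assign read-through / intra-chromosomal / inter-chromosomal."""
    g5, g3 = index.get(cand.five.gene_id), index.get(cand.three.gene_id)
    if g5.contig != g3.contig:
        return "inter-chromosomal"
    if g5.strand == g3.strand:
        # transcription runs left->right on '+', right->left on '-'
        if g5.strand == "+":
            gap = g3.span[0] - g5.span[1]
        else:
            gap = g5.span[0] - g3.span[1]
        if 0 <= gap <= readthrough_max_gap:
            return "read-through"
    return "intra-chromosomal"


def classify_all(
    candidates: list[ChimeraCandidate],
    index: AnnotationIndex,
    tolerance: int = 0,
    readthrough_max_gap: int = 100_000,
) -> list[ChimeraCandidate]:
    """Classify every candidate; a total function over parsed candidates."""
    return [
        replace(
            c,
            junction_class=classify_junction(c, index, tolerance),
            genomic_class=classify_genomic(c, index, readthrough_max_gap),
        )
        for c in candidates
    ]


# ---------------------------------------------------------------------------
# Catalog TSV I/O
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "chimera_id", "sample_id",
    "gene_5p", "contig_5p", "strand_5p", "breakpoint_5p",
    "gene_3p", "contig_3p", "strand_3p", "breakpoint_3p",
    "junction_seq", "score", "junction_class", "genomic_class",
]


def candidates_to_frame(candidates: list[ChimeraCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "chimera_id": c.chimera_id,
                "sample_id": c.sample_id,
                "gene_5p": c.five.gene_id,
                "contig_5p": c.five.contig,
                "strand_5p": c.five.strand,
                "breakpoint_5p": c.five.breakpoint + 1,
                "gene_3p": c.three.gene_id,
                "contig_3p": c.three.contig,
                "strand_3p": c.three.strand,
                "breakpoint_3p": c.three.breakpoint + 1,
                "junction_seq": c.junction_seq,
                "score": "" if c.score is None else c.score,
                "junction_class": c.junction_class or "",
                "genomic_class": c.genomic_class or "",
            }
        )
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def write_catalog(candidates: list[ChimeraCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path, index: AnnotationIndex) -> list[ChimeraCandidate]:
    """Read a classified catalog TSV back into candidates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: list[ChimeraCandidate] = []
    if df.empty:
        return out
    for row in df.itertuples(index=False):
        out.append(
            ChimeraCandidate(
                five=Partner(row.gene_5p, row.contig_5p, row.strand_5p, int(row.breakpoint_5p) - 1),
                three=Partner(row.gene_3p, row.contig_3p, row.strand_3p, int(row.breakpoint_3p) - 1),
                junction_seq=row.junction_seq,
                sample_id=row.sample_id,
                score=None if row.score in ("", None) or pd.isna(row.score) else float(row.score),
                junction_class=row.junction_class or None,
                genomic_class=row.genomic_class or None,
            )
        )
    return out
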