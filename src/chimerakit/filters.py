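"""The candidate-reduction cascade.

Stages, applied in this order:

1. ``filter_mm`` -- drop M/M-class candidates (neither breakpoint on an
   annotated exon boundary), the class with the lowest validation rate.
2. ``filter_recurrence`` -- keep chimeras carried by at least
   ``min_patients`` distinct patients (tumor + normal of one patient count
   once).
3. ``filter_alignment_uniqueness`` -- re-align the junction sequence to the
   genome with an internal seed-and-extend (ungapped) aligner and drop
   candidates explainable by a single contiguous genomic locus, or whose
   flanks do not align back to their parental loci.
4. ``flag_utr3_breakpoints`` -- set aside candidates whose 3' breakpoint
   falls in the 3' gene's 3'UTR (a class with a high false-positive rate).

Every stage returns a :class:`FilterReport`; reports always conserve
``n_in == n_removed + n_out`` and each filter is idempotent.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import AnnotationIndex, Genome
from .catalog import ChimeraCandidate
from .errors import ReferenceLookupError
from .seq import encode, revcomp


@dataclass
class FilterReport:
    """Accounting for one cascade stage."""

    stage: str
    n_in: int
    n_removed: int
    n_out: int
    #: removal reason per removed row, keyed by (chimera_id, sample_id)
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)
    notes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in == self.n_removed + self.n_out, "cascade conservation violated"

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "in": self.n_in,
            "removed": self.n_removed,
            "out": self.n_out,
        }


def write_report(reports: list[FilterReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_sample_to_patient(sample_id: str) -> str:
    """Map sample ids like ``P07_T`` / ``P07_N`` to patient ``P07``."""
    return sample_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# Stage 1: junction-class filter
# ---------------------------------------------------------------------------

def filter_mm(
    candidates: list[ChimeraCandidate],
) -> tuple[list[ChimeraCandidate], FilterReport]:
    """Remove all (and only) M/M-class candidates."""
    survivors, reasons = [], {}
    for c in candidates:
        if c.junction_class == "M/M":
            reasons[(c.chimera_id, c.sample_id)] = "junction class M/M"
        else:
            survivors.append(c)
    return survivors, FilterReport(
        "mm", len(candidates), len(reasons), len(survivors), reasons
    )


# ---------------------------------------------------------------------------
# Stage 2: cohort recurrence
# ---------------------------------------------------------------------------

def filter_recurrence(
    candidates: list[ChimeraCandidate],
    min_patients: int = 5,
    sample_to_patient=default_sample_to_patient,
) -> tuple[list[ChimeraCandidate], FilterReport]:
    """Keep chimeras seen in >= *min_patients* distinct patients."""
    patients: dict[str, set[str]] = defaultdict(set)
    for c in candidates:
        patients[c.chimera_id].add(sample_to_patient(c.sample_id))
    survivors, reasons = [], {}
    for c in candidates:
        n = len(patients[c.chimera_id])
        if n >= min_patients:
            survivors.append(c)
        else:
            reasons[(c.chimera_id, c.sample_id)] = f"recurrence {n} < {min_patients}"
    return survivors, FilterReport(
        "recurrence", len(candidates), len(reasons), len(survivors), reasons
    )


# ---------------------------------------------------------------------------
# Stage 3: junction-sequence re-alignment uniqueness
# ---------------------------------------------------------------------------

class SeedExtendAligner:
    """Exact k-mer seeding + ungapped identity scoring against a genome.

    A query placement is a (contig, strand, offset) triple found by hashing
    query k-mers against a genome k-mer index; its score is the fraction of
    identical bases over the in-bounds portion of the full query laid on the
    contig at that diagonal.  Ungapped placement suffices here because the
    filter only asks whether the query is plain contiguous genomic sequence.
    """

    def __init__(self, genome: Genome, seed_length: int = 11):
        self.seed_length = seed_length
        self.genome = genome
        self._enc: dict[str, np.ndarray] = {
            name: encode(rec.seq) for name, rec in genome.items()
        }
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = seed_length
        for name, rec in genome.items():
            s = rec.seq
            for i in range(len(s) - k + 1):
                self._index[s[i : i + k]].append((name, i))

    def _placements(self, query: str) -> set[tuple[str, str, int]]:
        k = self.seed_length
        hits: set[tuple[str, str, int]] = set()
        for strand, q in (("+", query), ("-", revcomp(query))):
            for j in range(0, len(q) - k + 1):
                for contig, pos in self._index.get(q[j : j + k], ()):
                    hits.add((strand, contig, pos - j))
        return hits

    def _score(self, query_enc: np.ndarray, contig: str, offset: int) -> tuple[float, float]:
        ref = self._enc[contig]
        qlen = len(query_enc)
        lo, hi = max(0, offset), min(len(ref), offset + qlen)
        if hi <= lo:
            return 0.0, 0.0
        matches = int(np.sum(ref[lo:hi] == query_enc[lo - offset : hi - offset]))
        overlap = hi - lo
        return matches / overlap, overlap / qlen

    def best_placement(
        self, query: str, contig: str | None = None, window: tuple[int, int] | None = None
    ) -> dict | None:
        """Best single contiguous placement of the full query.

        Optionally restricted to placements overlapping *window* on *contig*.
        Returns dict(identity, coverage, contig, strand, offset) or None.
        """
        best = None
        for strand, ctg, offset in self._placements(query):
            if contig is not None and ctg != contig:
                continue
            if window is not None:
                if offset + len(query) <= window[0] or offset >= window[1]:
                    continue
            q = query if strand == "+" else revcomp(query)
            ident, cov = self._score(encode(q), ctg, offset)
            key = (ident * cov, ident)
            if best is None or key > (best["identity"] * best["coverage"], best["identity"]):
                best = {
                    "identity": ident,
                    "coverage": cov,
                    "contig": ctg,
                    "strand": strand,
                    "offset": offset,
                }
        return best


def filter_alignment_uniqueness(
    candidates: list[ChimeraCandidate],
    genome: Genome,
    seed_length: int = 11,
    min_identity: float = 0.9,
    min_locus_coverage: float = 0.9,
    aligner: SeedExtendAligner | None = None,
) -> tuple[list[ChimeraCandidate], FilterReport]:
    """Drop candidates whose junction sequence is plain genomic sequence.

    A candidate is removed when its full junction sequence aligns contiguously
    to a single genomic locus at >= *min_identity* over >= *min_locus_coverage*
    of its length, or when either flank (half of the junction sequence) fails
    to align back to its annotated parental locus at >= *min_identity*.
    """
    for c in candidates:
        for partner in (c.five, c.three):
            if partner.contig not in genome:
                raise ReferenceLookupError(f"contig {partner.contig!r} not in genome")
    if aligner is None or aligner.seed_length != seed_length:
        aligner = SeedExtendAligner(genome, seed_length)
    survivors, reasons = [], {}
    # score each distinct junction sequence once
    verdict_cache: dict[tuple[str, str, str], str | None] = {}
    for c in candidates:
        key = (c.junction_seq, c.five.gene_id, c.three.gene_id)
        if key not in verdict_cache:
            verdict_cache[key] = _uniqueness_verdict(
                c, aligner, min_identity, min_locus_coverage
            )
        verdict = verdict_cache[key]
        if verdict is None:
            survivors.append(c)
        else:
            reasons[(c.chimera_id, c.sample_id)] = verdict
    return survivors, FilterReport(
        "uniqueness", len(candidates), len(reasons), len(survivors), reasons
    )


def _uniqueness_verdict(
    c: ChimeraCandidate,
    aligner: SeedExtendAligner,
    min_identity: float,
    min_locus_coverage: float,
) -> str | None:
    """Removal reason for one candidate, or None to keep it."""
    best = aligner.best_placement(c.junction_seq)
    if (
        best is not None
        and best["identity"] >= min_identity
        and best["coverage"] >= min_locus_coverage
    ):
        return (
            f"junction aligns contiguously to {best['contig']}:{best['offset']}"
            f" ({best['identity']:.2f} identity)"
        )
    mid = len(c.junction_seq) // 2
    flanks = (
        ("5p", c.junction_seq[:mid], c.five),
        ("3p", c.junction_seq[mid:], c.three),
    )
    for side, flank, partner in flanks:
        hit = aligner.best_placement(flank, contig=partner.contig)
        if hit is None or hit["identity"] < min_identity or hit["coverage"] < min_locus_coverage:
            return f"{side} flank does not align to parental locus"
    return None


# ---------------------------------------------------------------------------
# Stage 4: 3'UTR breakpoint flagging
# ---------------------------------------------------------------------------

def flag_utr3_breakpoints(
    candidates: list[ChimeraCandidate], index: AnnotationIndex
) -> tuple[list[ChimeraCandidate], list[ChimeraCandidate], FilterReport]:
    """Move candidates with a 3' breakpoint inside the 3' gene's 3'UTR aside.

    Genes whose 3'UTR cannot be determined (no annotation, no CDS) keep their
    candidates, marked ``undeterminable`` in the report notes.
    """
    survivors, flagged, reasons, notes = [], [], {}, {}
    for c in candidates:
        gene = index.get(c.three.gene_id)
        utr3 = gene.effective_utr3()
        if utr3 is None:
            notes[(c.chimera_id, c.sample_id)] = "utr3 undeterminable"
            survivors.append(c)
        elif any(s <= c.three.breakpoint < e for s, e in utr3):
            reasons[(c.chimera_id, c.sample_id)] = "3' breakpoint in 3'UTR"
            flagged.append(c)
        else:
            survivors.append(c)
    report = FilterReport(
        "utr3", len(candidates), len(flagged), len(survivors), reasons, notes
    )
    return survivors, flagged, report


# ---------------------------------------------------------------------------
# Whole cascade
# ---------------------------------------------------------------------------

def run_cascade(
    candidates: list[ChimeraCandidate],
    genome: Genome,
    index: AnnotationIndex,
    min_patients: int = 5,
    seed_length: int = 11,
    min_identity: float = 0.9,
    sample_to_patient=default_sample_to_patient,
) -> tuple[list[ChimeraCandidate], list[ChimeraCandidate], list[FilterReport]]:
    """M/M -> recurrence -> uniqueness -> 3'UTR, in the documented order.

    Returns (survivors, utr3_flagged, reports).  The order matters: the
    recurrence tally is taken after M/M removal.
    """
    reports = []
    cur, rep = filter_mm(candidates)
    reports.append(rep)
    cur, rep = filter_recurrence(cur, min_patients, sample_to_patient)
    reports.append(rep)
    cur, rep = filter_alignment_uniqueness(cur, genome, seed_length, min_identity)
    reports.append(rep)
    cur, flagged, rep = flag_utr3_breakpoints(cur, index)
    reports.append(rep)
    return cur, flagged, reports
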