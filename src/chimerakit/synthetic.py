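"""Synthetic fusion-cohort generator.

Builds a toy annotated genome, plants chimeric transcripts of every junction
class (E/E, E/M, M/E, M/M) and genomic class (read-through,
intra-chromosomal, inter-chromosomal), simulates junction-covering short and
long reads with sequencing error, emits an EricScript-like candidate table
(including optional contiguous-genomic decoy candidates), and draws a
clinical cohort whose biochemical-recurrence hazard depends on read-through
chimera burden.

Everything is deterministic under ``SimulationConfig.seed``: each stage
draws from an independent child of one root ``numpy`` SeedSequence, so the
same config yields byte-identical output files.

Reads carry provenance in their FASTQ identifiers
(``sample:serial|src=<transcript>|span=<0/1>``) so that junction-read counts
can be audited from read names alone, without alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationIndex,
    GeneModel,
    Genome,
    GenomeSequence,
    write_annotation,
    write_genome,
)
from .errors import ConfigError, PlantingError
from .seq import revcomp

log = logging.getLogger(__name__)

JUNCTION_CLASSES = ("E/E", "E/M", "M/E", "M/M")
GENOMIC_CLASSES = ("read-through", "intra-chromosomal", "inter-chromosomal")

#: transcription-interior margin (nt) kept between an M-class breakpoint and
#: the nearest exon edge, so planted M labels can never collide with an
#: annotated boundary and junction flanks stay within one exon.
M_MARGIN = 55


@dataclass(frozen=True)
class FusionSpec:
    """One planted chimera: its classes, recurrence and tumor/normal ratio."""

    junction_class: str
    genomic_class: str
    n_patients: int = 5
    tumor_normal_ratio: float = 1.0
    in_utr3: bool = False  # place the 3' breakpoint inside the 3' gene's 3'UTR


def default_fusion_plan(
    n_per_combo: int = 2,
    recurrences: tuple[int, ...] = (4, 5, 6, 8),
    n_differential: int = 3,
    differential_ratio: float = 4.0,
    differential_recurrence: int = 30,
    n_utr3: int = 2,
) -> list[FusionSpec]:
    """A demonstration plan covering every class combination.

    ``n_per_combo`` chimeras per junction x genomic class combination with
    recurrence cycling through *recurrences*; the first *n_differential*
    non-M/M chimeras get a tumor/normal junction-read ratio of
    *differential_ratio* and are carried by *differential_recurrence*
    patients (the whole default cohort, since the paired test only sees
    carrier pairs); *n_utr3* extra E/M chimeras have their 3' breakpoint
    planted inside the 3'UTR.
    """
    plan: list[FusionSpec] = []
    i = 0
    diff_left = n_differential
    for jc in JUNCTION_CLASSES:
        for gc in GENOMIC_CLASSES:
            for _ in range(n_per_combo):
                ratio, rec = 1.0, recurrences[i % len(recurrences)]
                if jc != "M/M" and diff_left > 0:
                    ratio, rec = differential_ratio, differential_recurrence
                    diff_left -= 1
                plan.append(FusionSpec(jc, gc, rec, ratio))
                i += 1
    for j in range(n_utr3):
        plan.append(
            FusionSpec("E/M", GENOMIC_CLASSES[j % 3], recurrences[j % len(recurrences)],
                       1.0, in_utr3=True)
        )
    return plan


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults give a small full-feature cohort."""

    seed: int = 0
    # genome / annotation
    contig_lengths: tuple[int, ...] = (200_000, 200_000)
    genes_per_contig: int = 30
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 400)
    intergenic_gap: tuple[int, int] = (300, 600)
    utr3_length: tuple[int, int] = (60, 120)
    strand_persistence: float = 0.7  # P(next gene keeps the previous strand)
    # chimeras
    fusions: list[FusionSpec] = field(default_factory=default_fusion_plan)
    n_decoys: int = 4
    candidate_flank: int = 50  # junction-sequence flank in the candidate table
    # cohort / reads
    n_patients: int = 30
    short_read_length: int = 100
    parental_coverage: float = 2.0
    chimeric_coverage: float = 6.0
    short_error_rate: float = 0.002
    junction_flank: int = 20  # margin defining a junction-spanning short read
    long_read_length: tuple[int, int] = (400, 1000)
    long_coverage: float = 3.0
    long_error_rate: float = 0.08
    long_indel_fraction: float = 0.4  # fraction of long-read errors that are indels
    long_flank: int = 30  # margin defining a junction-spanning long read
    # survival / grade
    baseline_hazard: float = 0.01
    log_hazard_ratio: float = math.log(3.0)
    censoring_rate: float = 0.3
    gleason_enrichment: float = 0.25

    def __post_init__(self) -> None:
        for name in ("short_error_rate", "long_error_rate", "long_indel_fraction",
                     "censoring_rate", "strand_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.baseline_hazard < 0:
            raise ConfigError("baseline_hazard must be >= 0")
        for f in self.fusions:
            if f.junction_class not in JUNCTION_CLASSES:
                raise ConfigError(f"unknown junction class {f.junction_class!r}")
            if f.genomic_class not in GENOMIC_CLASSES:
                raise ConfigError(f"unknown genomic class {f.genomic_class!r}")
            if f.n_patients > self.n_patients:
                raise ConfigError(
                    f"fusion recurrence {f.n_patients} exceeds cohort size {self.n_patients}"
                )

    @property
    def patients(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_patients + 1)]

    def rng_for(self, stage: str) -> np.random.Generator:
        """Independent, order-insensitive stream per named stage."""
        stages = ("genome", "plant", "decoys", "short_reads", "long_reads", "cohort")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stages.index(stage),))
        )


@dataclass
class TruthRecord:
    """Ground truth for one planted chimera."""

    chimera_id: str
    gene_5p: str
    gene_3p: str
    contig_5p: str
    strand_5p: str
    breakpoint_5p: int  # 0-based junction-adjacent base
    contig_3p: str
    strand_3p: str
    breakpoint_3p: int
    junction_class: str
    genomic_class: str
    in_utr3: bool
    tumor_normal_ratio: float
    carriers: list[str]
    transcript: str
    junction_offset: int  # transcript index of the first 3'-gene base
    short_counts: dict[str, int] = field(default_factory=dict)
    long_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[Genome, AnnotationIndex]:
    """Random genome with non-overlapping genes laid along each contig.

    Strands are drawn with persistence so same-strand neighbor pairs (the
    substrate for read-through planting) always exist at the default sizes.
    """
    rng = config.rng_for("genome")
    genome = Genome()
    genes: list[GeneModel] = []
    for ci, clen in enumerate(config.contig_lengths):
        name = f"chr{ci + 1}"
        bases = rng.integers(0, 4, size=clen)
        genome[name] = GenomeSequence(name, "".join("ACGT"[b] for b in bases))
        cursor = 200
        strand = "+" if rng.random() < 0.5 else "-"
        for gi in range(config.genes_per_contig):
            if rng.random() > config.strand_persistence:
                strand = "+" if strand == "-" else "-"
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
            in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                                   max(n_ex - 1, 0))
            span = int(ex_lens.sum() + in_lens.sum())
            if cursor + span > clen - 200:
                raise ConfigError(
                    f"contig {name} ({clen} bp) cannot fit {config.genes_per_contig} genes: "
                    f"gene {gi + 1} would end at {cursor + span}"
                )
            exons = []
            pos = cursor
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k])))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    pos += int(in_lens[k])
            utr_len = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
            # 3'UTR occupies the transcription-terminal end of the last exon
            if strand == "+":
                ls, le = exons[-1]
                utr3 = [(le - utr_len, le)]
            else:
                ls, le = exons[0]
                utr3 = [(ls, ls + utr_len)]
            cds = _exons_minus(exons, utr3)
            gid = f"G{ci + 1}_{gi + 1:03d}"
            genes.append(GeneModel(gid, name, strand, exons, utr3=utr3, cds=cds))
            cursor = pos + int(
                rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
            )
    return genome, AnnotationIndex(genes)


def _exons_minus(exons: list[tuple[int, int]], cut: list[tuple[int, int]]):
    out = []
    for s, e in exons:
        segs = [(s, e)]
        for cs, ce in cut:
            nxt = []
            for a, b in segs:
                if ce <= a or cs >= b:
                    nxt.append((a, b))
                else:
                    if a < cs:
                        nxt.append((a, cs))
                    if ce < b:
                        nxt.append((ce, b))
            segs = nxt
        out.extend(segs)
    return out


# ---------------------------------------------------------------------------
# Chimera planting
# ---------------------------------------------------------------------------

def _tx_exons(gene: GeneModel) -> list[tuple[int, int]]:
    """Exons in transcription order."""
    return gene.exons if gene.strand == "+" else list(reversed(gene.exons))


def _pick_breakpoint(
    gene: GeneModel, side: str, cls: str, rng: np.random.Generator, in_utr3: bool = False
) -> int:
    """Genomic position (0-based) of the junction-adjacent base for one side."""
    tx = _tx_exons(gene)
    n = len(tx)
    if in_utr3:
        (us, ue) = gene.utr3[0]
        # keep >= candidate-flank room downstream of the breakpoint in the UTR
        if gene.strand == "+":
            lo, hi = us + 1, ue - 52
        else:
            lo, hi = us + 52, ue - 1
        return int(rng.integers(lo, hi))
    if cls == "E":
        if side == "5p":
            s, e = tx[int(rng.integers(0, n - 1))]  # donor: end of a non-last exon
            return e - 1 if gene.strand == "+" else s
        s, e = tx[int(rng.integers(1, n))]  # acceptor: start of a non-first exon
        return s if gene.strand == "+" else e - 1
    # M: strictly interior, away from edges, never in the terminal (UTR) exon
    lo_ex = 0 if side == "5p" else 1
    hi_ex = n - 1  # exclude the transcription-last exon
    t = int(rng.integers(lo_ex, max(hi_ex, lo_ex + 1)))
    s, e = tx[t]
    return int(rng.integers(s + M_MARGIN, e - M_MARGIN))


def _partner_pools(index: AnnotationIndex, config: SimulationConfig):
    """Eligible (5', 3') gene pairs per genomic class."""
    rt, intra, inter = [], [], []
    by_contig = {}
    for g in index.genes.values():
        by_contig.setdefault(g.contig, []).append(g)
    for contig, gs in by_contig.items():
        gs.sort(key=lambda g: g.span)
        for a, b in zip(gs, gs[1:]):
            if a.strand == b.strand:
                rt.append((a, b) if a.strand == "+" else (b, a))
        for i, a in enumerate(gs):
            for b in gs[i + 1 :]:
                if a.strand != b.strand:
                    intra.append((a, b))
    contigs = sorted(by_contig)
    for i, c1 in enumerate(contigs):
        for c2 in contigs[i + 1 :]:
            for a in by_contig[c1]:
                for b in by_contig[c2]:
                    inter.append((a, b))
    return {"read-through": rt, "intra-chromosomal": intra, "inter-chromosomal": inter}


def plant_chimeras(
    config: SimulationConfig, index: AnnotationIndex, genome: Genome
) -> list[TruthRecord]:
    """Construct one chimeric transcript per FusionSpec, with ground truth."""
    rng = config.rng_for("plant")
    pools = _partner_pools(index, config)
    for pool in pools.values():
        rng.shuffle(pool)
    cursors = {k: 0 for k in pools}
    patients = config.patients
    truth: list[TruthRecord] = []
    for spec in config.fusions:
        pool = pools[spec.genomic_class]
        if cursors[spec.genomic_class] >= len(pool):
            raise PlantingError(
                f"no eligible partner pair left for genomic class {spec.genomic_class!r}"
            )
        g5, g3 = pool[cursors[spec.genomic_class]]
        cursors[spec.genomic_class] += 1
        jc5, jc3 = spec.junction_class.split("/")
        bp5 = _pick_breakpoint(g5, "5p", jc5, rng)
        bp3 = _pick_breakpoint(g3, "3p", jc3, rng, in_utr3=spec.in_utr3)
        t5 = g5.spliced_sequence(genome)
        t3 = g3.spliced_sequence(genome)
        cut5 = g5.transcript_offset(bp5) + 1
        cut3 = g3.transcript_offset(bp3)
        transcript = t5[:cut5] + t3[cut3:]
        carriers = sorted(rng.choice(patients, size=spec.n_patients, replace=False))
        truth.append(
            TruthRecord(
                chimera_id=f"{g5.gene_id}--{g3.gene_id}@{bp5}:{bp3}",
                gene_5p=g5.gene_id, gene_3p=g3.gene_id,
                contig_5p=g5.contig, strand_5p=g5.strand, breakpoint_5p=bp5,
                contig_3p=g3.contig, strand_3p=g3.strand, breakpoint_3p=bp3,
                junction_class=spec.junction_class,
                genomic_class=spec.genomic_class,
                in_utr3=spec.in_utr3,
                tumor_normal_ratio=spec.tumor_normal_ratio,
                carriers=list(carriers),
                transcript=transcript,
                junction_offset=cut5,
            )
        )
    return truth


def make_decoy_candidates(
    config: SimulationConfig,
    index: AnnotationIndex,
    genome: Genome,
    exclude_pairs: set[tuple[str, str]] = frozenset(),
) -> pd.DataFrame:
    """Decoy candidate rows whose 'junction' is one contiguous genomic window.

    Breakpoints sit on exon boundaries of a same-strand neighbor pair (E/E
    read-through-like) and each decoy recurs widely, so decoys survive the
    junction-class and recurrence stages and must be caught by the
    re-alignment uniqueness filter.
    """
    rng = config.rng_for("decoys")
    pools = [
        (a, b)
        for a, b in _partner_pools(index, config)["read-through"]
        if (a.gene_id, b.gene_id) not in exclude_pairs
    ]
    rng.shuffle(pools)
    if config.n_decoys > len(pools):
        raise PlantingError("not enough neighbor pairs for the requested decoys")
    width = 2 * config.candidate_flank
    rows = []
    contigs = sorted(genome)
    for i in range(config.n_decoys):
        g5, g3 = pools[i]
        bp5 = _pick_breakpoint(g5, "5p", "E", rng)
        bp3 = _pick_breakpoint(g3, "3p", "E", rng)
        contig = contigs[int(rng.integers(len(contigs)))]
        start = int(rng.integers(0, len(genome[contig].seq) - width))
        seq = genome[contig].seq[start : start + width]
        n_carriers = min(config.n_patients, 6)
        carriers = sorted(rng.choice(config.patients, size=n_carriers, replace=False))
        for pat in carriers:
            rows.append(
                {
                    "sample_id": f"{pat}_T",
                    "gene_5p": g5.gene_id, "contig_5p": g5.contig,
                    "strand_5p": g5.strand, "breakpoint_5p": bp5 + 1,
                    "gene_3p": g3.gene_id, "contig_3p": g3.contig,
                    "strand_3p": g3.strand, "breakpoint_3p": bp3 + 1,
                    "junction_seq": seq,
                    "score": 0.5,
                    "decoy_id": f"{g5.gene_id}--{g3.gene_id}@{bp5}:{bp3}",
                }
            )
    return pd.DataFrame(rows)


def candidate_table(config: SimulationConfig, truth: list[TruthRecord]) -> pd.DataFrame:
    """EricScript-like candidate rows: one per chimera per carrier tumor sample."""
    L = config.candidate_flank
    rows = []
    for t in truth:
        j = t.junction_offset
        seq = t.transcript[j - L : j + L]
        for pat in t.carriers:
            rows.append(
                {
                    "sample_id": f"{pat}_T",
                    "gene_5p": t.gene_5p, "contig_5p": t.contig_5p,
                    "strand_5p": t.strand_5p, "breakpoint_5p": t.breakpoint_5p + 1,
                    "gene_3p": t.gene_3p, "contig_3p": t.contig_3p,
                    "strand_3p": t.strand_3p, "breakpoint_3p": t.breakpoint_3p + 1,
                    "junction_seq": seq,
                    "score": 0.9,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_substitutions(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=min(n_err, len(arr)), replace=False)
    for p in pos:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _apply_long_errors(
    seq: str, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Substitutions plus insertions/deletions at the long-read error rate."""
    e = config.long_error_rate
    if e == 0:
        return seq
    p_ind = e * config.long_indel_fraction
    p_sub = e - p_ind
    n = len(seq)
    n_sub = rng.binomial(n, p_sub)
    n_ins = rng.binomial(n, p_ind / 2)
    n_del = rng.binomial(n, p_ind / 2)
    seq = _apply_substitutions(seq, n_sub, rng)
    chars = list(seq)
    for _ in range(n_del):
        if chars:
            chars.pop(int(rng.integers(len(chars))))
    for _ in range(n_ins):
        chars.insert(int(rng.integers(len(chars) + 1)), "ACGT"[int(rng.integers(4))])
    return "".join(chars)


def _sample_ids(config: SimulationConfig) -> list[str]:
    return [f"{p}_{k}" for p in config.patients for k in ("T", "N")]


def _write_fastq(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_short_reads(
    config: SimulationConfig,
    index: AnnotationIndex,
    genome: Genome,
    truth: list[TruthRecord],
    outdir: str | Path,
) -> dict[str, Path]:
    """Per-sample single-end FASTQ; fills ``TruthRecord.short_counts``.

    Reads are drawn uniformly along every parental transcript at
    ``parental_coverage`` and along each carried chimeric transcript at
    ``chimeric_coverage`` (times ``tumor_normal_ratio`` in the carrier's
    tumor sample).  A chimeric read is junction-spanning when it covers
    ``junction_flank`` bases on both sides of the junction before errors.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r = config.short_read_length
    parental = {
        gid: g.spliced_sequence(genome) for gid, g in sorted(index.genes.items())
    }
    carried: dict[str, list[TruthRecord]] = {}
    for t in truth:
        for pat in t.carriers:
            carried.setdefault(pat, []).append(t)
    root = np.random.SeedSequence(config.seed, spawn_key=(3,))
    sample_seeds = root.spawn(2 * config.n_patients)
    paths: dict[str, Path] = {}
    for si, sample in enumerate(_sample_ids(config)):
        rng = np.random.default_rng(sample_seeds[si])
        patient, kind = sample.rsplit("_", 1)
        records: list[tuple[str, str]] = []
        serial = 0

        def emit(tid: str, seq: str, coverage: float, junction: int | None, t=None):
            nonlocal serial
            L = len(seq)
            if L < r:
                log.warning("transcript %s (%d bp) shorter than read length; skipped", tid, L)
                return
            n = rng.poisson(coverage * L / r)
            if n == 0:
                return
            starts = rng.integers(0, L - r + 1, size=n)
            n_errs = rng.binomial(r, config.short_error_rate, size=n)
            flips = rng.random(n) < 0.5
            for idx in range(n):
                s = int(starts[idx])
                span = 0
                if junction is not None and s <= junction - config.junction_flank \
                        and s + r >= junction + config.junction_flank:
                    span = 1
                    t.short_counts[sample] = t.short_counts.get(sample, 0) + 1
                read = seq[s : s + r]
                read = _apply_substitutions(read, int(n_errs[idx]), rng)
                if flips[idx]:
                    read = revcomp(read)
                records.append((f"{sample}:{serial}|src={tid}|span={span}", read))
                serial += 1

        for gid, seq in parental.items():
            emit(gid, seq, config.parental_coverage, None)
        for t in carried.get(patient, []):
            cov = config.chimeric_coverage * (t.tumor_normal_ratio if kind == "T" else 1.0)
            emit(t.chimera_id, t.transcript, cov, t.junction_offset, t)
        path = outdir / f"{sample}.short.fastq"
        _write_fastq(path, records)
        paths[sample] = path
    return paths


def simulate_long_reads(
    config: SimulationConfig,
    index: AnnotationIndex,
    genome: Genome,
    truth: list[TruthRecord],
    outdir: str | Path,
) -> dict[str, Path]:
    """Per-sample long-read FASTQ (substitutions + indels); fills long_counts.

    Long reads are drawn from carried chimeric transcripts and from the
    parental transcripts of every partner gene (the single-flank negative
    control for anchored validation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lo, hi = config.long_read_length
    partner_genes = sorted({t.gene_5p for t in truth} | {t.gene_3p for t in truth})
    parental = {gid: index.get(gid).spliced_sequence(genome) for gid in partner_genes}
    carried: dict[str, list[TruthRecord]] = {}
    for t in truth:
        for pat in t.carriers:
            carried.setdefault(pat, []).append(t)
    root = np.random.SeedSequence(config.seed, spawn_key=(4,))
    sample_seeds = root.spawn(2 * config.n_patients)
    mean_len = (lo + hi) / 2
    paths: dict[str, Path] = {}
    for si, sample in enumerate(_sample_ids(config)):
        rng = np.random.default_rng(sample_seeds[si])
        patient, _ = sample.rsplit("_", 1)
        records: list[tuple[str, str]] = []
        serial = 0

        def emit(tid: str, seq: str, junction: int | None, t=None):
            nonlocal serial
            L = len(seq)
            n = rng.poisson(config.long_coverage * L / mean_len)
            for _ in range(n):
                rl = int(rng.integers(lo, hi + 1))
                rl = min(rl, L)
                s = int(rng.integers(0, L - rl + 1))
                span = 0
                # pre-error junction overlap margin: bases on the thinner side
                jmargin = 0
                if junction is not None:
                    jmargin = max(0, min(junction - s, s + rl - junction))
                    if jmargin >= config.long_flank:
                        span = 1
                        t.long_counts[sample] = t.long_counts.get(sample, 0) + 1
                read = _apply_long_errors(seq[s : s + rl], config, rng)
                if rng.random() < 0.5:
                    read = revcomp(read)
                records.append(
                    (f"{sample}:{serial}|src={tid}|span={span}|jmargin={jmargin}", read)
                )
                serial += 1

        for gid, seq in parental.items():
            emit(gid, seq, None)
        for t in carried.get(patient, []):
            emit(t.chimera_id, t.transcript, t.junction_offset, t)
        path = outdir / f"{sample}.long.fastq"
        _write_fastq(path, records)
        paths[sample] = path
    return paths


def audit_junction_margins(fastq_path: str | Path) -> dict[str, int]:
    """Largest pre-error junction-overlap margin per source transcript,
    recounted from long-read names."""
    best: dict[str, int] = {}
    with open(fastq_path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 0:
                fields = dict(
                    kv.split("=", 1) for kv in line.strip().split("|")[1:] if "=" in kv
                )
                if "jmargin" in fields:
                    src = fields["src"]
                    best[src] = max(best.get(src, 0), int(fields["jmargin"]))
    return best


def audit_span_counts(fastq_path: str | Path) -> dict[str, int]:
    """Recount junction-spanning reads per source transcript from read names."""
    counts: dict[str, int] = {}
    with open(fastq_path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 0:
                fields = dict(
                    kv.split("=", 1) for kv in line.strip().split("|")[1:] if "=" in kv
                )
                if fields.get("span") == "1":
                    src = fields["src"]
                    counts[src] = counts.get(src, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

def simulate_survival(
    burden: np.ndarray,
    baseline_hazard: float,
    log_hazard_ratio: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard h0*exp(beta*burden) and
    independent exponential censoring calibrated to *censoring_rate* at
    baseline hazard; returns (time, event)."""
    if baseline_hazard <= 0:
        raise ConfigError("baseline_hazard must be > 0 for survival simulation")
    haz = baseline_hazard * np.exp(log_hazard_ratio * np.asarray(burden, dtype=float))
    t_event = rng.exponential(1.0 / haz)
    if censoring_rate > 0:
        lam_c = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=len(t_event))
    else:
        t_cens = np.full(len(t_event), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def true_burden(config: SimulationConfig, truth: list[TruthRecord]) -> pd.Series:
    """Per-patient count of distinct planted read-through chimeras."""
    counts = {p: 0 for p in config.patients}
    for t in truth:
        if t.genomic_class == "read-through":
            for pat in t.carriers:
                counts[pat] += 1
    return pd.Series(counts, name="true_burden")


def simulate_cohort(config: SimulationConfig, truth: list[TruthRecord]) -> pd.DataFrame:
    """Clinical table whose BCR hazard and Gleason grade depend on burden."""
    if config.n_patients < 2:
        raise ConfigError("need at least 2 patients")
    rng = config.rng_for("cohort")
    b = true_burden(config, truth).to_numpy(dtype=float)
    time, event = simulate_survival(
        b, config.baseline_hazard, config.log_hazard_ratio, config.censoring_rate, rng
    )
    scores = np.arange(6, 11)
    base = np.array([0.35, 0.30, 0.18, 0.10, 0.07])
    gleason = np.empty(config.n_patients, dtype=int)
    for i in range(config.n_patients):
        w = base * np.exp(config.gleason_enrichment * b[i] * (scores - 6))
        gleason[i] = rng.choice(scores, p=w / w.sum())
    return pd.DataFrame(
        {
            "patient_id": config.patients,
            "tumor_sample_id": [f"{p}_T" for p in config.patients],
            "normal_sample_id": [f"{p}_N" for p in config.patients],
            "bcr_time": np.round(time, 4),
            "bcr_event": event,
            "gleason": gleason,
        }
    )


# ---------------------------------------------------------------------------
# Truth-table I/O and one-call convenience
# ---------------------------------------------------------------------------

def truth_to_frames(truth: list[TruthRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(chimera table, per-sample junction-read count table)."""
    chim = pd.DataFrame(
        [
            {
                "chimera_id": t.chimera_id,
                "gene_5p": t.gene_5p, "gene_3p": t.gene_3p,
                "junction_class": t.junction_class,
                "genomic_class": t.genomic_class,
                "in_utr3": int(t.in_utr3),
                "tumor_normal_ratio": t.tumor_normal_ratio,
                "breakpoint_5p": t.breakpoint_5p,
                "breakpoint_3p": t.breakpoint_3p,
                "junction_offset": t.junction_offset,
                "transcript_length": len(t.transcript),
                "carriers": ",".join(t.carriers),
            }
            for t in truth
        ]
    )
    counts = pd.DataFrame(
        [
            {"chimera_id": t.chimera_id, "sample_id": s,
             "short_junction_reads": t.short_counts.get(s, 0),
             "long_junction_reads": t.long_counts.get(s, 0)}
            for t in truth
            for s in sorted(set(t.short_counts) | set(t.long_counts))
        ],
        columns=["chimera_id", "sample_id", "short_junction_reads", "long_junction_reads"],
    )
    return chim, counts


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Genome
    index: AnnotationIndex
    truth: list[TruthRecord]
    candidates: pd.DataFrame
    decoys: pd.DataFrame
    clinical: pd.DataFrame
    short_fastqs: dict[str, Path]
    long_fastqs: dict[str, Path]


def simulate_all(
    config: SimulationConfig,
    outdir: str | Path,
    reads: bool = True,
    long_reads: bool = True,
) -> SimulationResult:
    """Run the whole generator and write every artifact under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, index = simulate_genome_and_annotation(config)
    write_genome(genome, outdir / "genome.fa")
    write_annotation(index, outdir / "annotation.gtf")
    truth = plant_chimeras(config, index, genome)
    decoys = make_decoy_candidates(
        config, index, genome, exclude_pairs={(t.gene_5p, t.gene_3p) for t in truth}
    )
    cands = candidate_table(config, truth)
    if len(decoys):
        cands = pd.concat([cands, decoys.drop(columns=["decoy_id"])], ignore_index=True)
    cands.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    short_fastqs: dict[str, Path] = {}
    long_fastqs: dict[str, Path] = {}
    if reads:
        short_fastqs = simulate_short_reads(config, index, genome, truth, outdir / "reads_short")
    if long_reads:
        long_fastqs = simulate_long_reads(config, index, genome, truth, outdir / "reads_long")
    clinical = simulate_cohort(config, truth)
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    chim, counts = truth_to_frames(truth)
    chim.to_csv(outdir / "truth_chimeras.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "truth_counts.tsv", sep="\t", index=False)
    if len(decoys):
        decoys[["decoy_id"]].drop_duplicates().to_csv(
            outdir / "truth_decoys.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["decoy_id"]).to_csv(
            outdir / "truth_decoys.tsv", sep="\t", index=False
        )
    return SimulationResult(
        config, genome, index, truth, cands, decoys, clinical, short_fastqs, long_fastqs
    )
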