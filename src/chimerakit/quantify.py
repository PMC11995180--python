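"""Junction-spanning read quantification by bit-parallel approximate matching.

The junction search pattern is the 2L-mer centred on the fusion junction
(L transcript bases on each side).  Reads are scanned with the shift-and
(Baeza-Yates--Gonnet / Wu--Manber) automaton under a Hamming mismatch budget
k: state word R_d has bit j set iff the pattern prefix of length j+1 matches
the text ending at the current position with at most d mismatches,

    R_0' = ((R_0 << 1) | 1) & mask[c]
    R_d' = (((R_d << 1) | 1) & mask[c]) | ((R_{d-1} << 1) | 1)

A read supports a pattern if the full-pattern bit fires anywhere in the read
(or in its reverse complement when both strands are searched); each read
counts at most once per pattern.  Patterns are limited to 64 nt so a state
fits one machine word; the module runs the recurrence across all reads of a
sample at once with numpy uint64 lanes.

Differential support between paired tumor/normal samples uses
counts-per-million normalisation, a paired Wilcoxon signed-rank test per
chimera and Benjamini-Hochberg correction across chimeras.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import AnnotationIndex, Genome
from .catalog import ChimeraCandidate
from .errors import AnalysisError, PatternError
from .seq import encode_reads, revcomp

_ONE = np.uint64(1)


@dataclass(frozen=True)
class JunctionPattern:
    """A 2L-mer junction query with flank length L and mismatch budget k."""

    chimera_id: str
    pattern: str
    flank: int
    max_mismatches: int

    def __post_init__(self) -> None:
        if self.flank < 10:
            raise PatternError(f"{self.chimera_id}: flank {self.flank} < 10")
        if self.max_mismatches > self.flank / 5:
            raise PatternError(
                f"{self.chimera_id}: k={self.max_mismatches} exceeds L/5={self.flank / 5:g}"
            )
        if len(self.pattern) > 64:
            raise PatternError(
                f"{self.chimera_id}: pattern length {len(self.pattern)} > 64; "
                "use the long-read (edit distance) path"
            )
        if set(self.pattern) - set("ACGT"):
            raise PatternError(f"{self.chimera_id}: pattern contains non-ACGT characters")


def build_pattern(
    cand: ChimeraCandidate,
    flank: int = 20,
    max_mismatches: int = 2,
    index: AnnotationIndex | None = None,
    genome: Genome | None = None,
) -> JunctionPattern:
    """Build the junction pattern for one candidate.

    The candidate's junction sequence is taken to be centred on the junction
    (the catalog schema guarantees this); when it is too short and a genome +
    annotation are supplied, the flanks are reconstructed from the spliced
    parental transcripts instead.
    """
    seq = cand.junction_seq
    mid = len(seq) // 2
    if mid >= flank and len(seq) - mid >= flank:
        pat = seq[mid - flank : mid + flank]
    elif index is not None and genome is not None:
        pat = _pattern_from_annotation(cand, flank, index, genome)
    else:
        raise PatternError(
            f"{cand.chimera_id}: junction sequence too short for flank {flank} "
            "and no genome/annotation to reconstruct from"
        )
    return JunctionPattern(cand.chimera_id, pat, flank, max_mismatches)


def _pattern_from_annotation(
    cand: ChimeraCandidate, flank: int, index: AnnotationIndex, genome: Genome
) -> str:
    g5, g3 = index.get(cand.five.gene_id), index.get(cand.three.gene_id)
    for g, p in ((g5, cand.five), (g3, cand.three)):
        if not g.exonic(p.breakpoint):
            raise PatternError(
                f"{cand.chimera_id}: breakpoint {p.breakpoint} of {g.gene_id} is "
                "not exonic; flanks unreconstructable"
            )
    t5 = g5.spliced_sequence(genome)
    t3 = g3.spliced_sequence(genome)
    cut5 = g5.transcript_offset(cand.five.breakpoint) + 1  # include the bp base
    cut3 = g3.transcript_offset(cand.three.breakpoint)
    if cut5 < flank or len(t3) - cut3 < flank:
        raise PatternError(f"{cand.chimera_id}: flank {flank} exceeds a spliced segment")
    return t5[cut5 - flank : cut5] + t3[cut3 : cut3 + flank]


# ---------------------------------------------------------------------------
# Bitap
# ---------------------------------------------------------------------------

def _char_masks(pattern: str) -> np.ndarray:
    """Per-symbol match masks for codes A,C,G,T,N,pad; N and pad match nothing."""
    masks = np.zeros(6, dtype=np.uint64)
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, ch in enumerate(pattern):
        masks[lut[ch]] |= np.uint64(1) << np.uint64(i)
    return masks


def bitap_match(pattern: str, text: str, k: int) -> bool:
    """Scalar shift-and scan: does *text* contain *pattern* with <= k mismatches?

    Reference implementation on Python ints; `_bitap_match_many` is the
    vectorised production path.
    """
    m = len(pattern)
    if m == 0 or m > 64:
        raise PatternError(f"pattern length {m} outside 1..64")
    masks = {c: 0 for c in "ACGTN"}
    for i, ch in enumerate(pattern):
        masks[ch] |= 1 << i
    goal = 1 << (m - 1)
    r = [0] * (k + 1)
    for ch in text:
        mask = masks.get(ch, 0)
        prev = r[:]
        r[0] = ((prev[0] << 1) | 1) & mask
        for d in range(1, k + 1):
            r[d] = ((((prev[d] << 1) | 1) & mask) | ((prev[d - 1] << 1) | 1))
        if r[k] & goal:
            return True
    return False


def _bitap_match_many(pattern: str, enc_reads: np.ndarray, k: int) -> np.ndarray:
    """Boolean array: which encoded reads contain the pattern (<= k mismatches)."""
    n, width = enc_reads.shape
    if n == 0:
        return np.zeros(0, dtype=bool)
    m = len(pattern)
    masks = _char_masks(pattern)
    goal = _ONE << np.uint64(m - 1)
    r = np.zeros((k + 1, n), dtype=np.uint64)
    found = np.zeros(n, dtype=bool)
    for j in range(width):
        col_mask = masks[np.minimum(enc_reads[:, j], 5)]
        prev0 = r[0]
        shifted_prev = ((prev0 << _ONE) | _ONE)
        r0_new = shifted_prev & col_mask
        carry = shifted_prev  # ((R_{d-1} << 1) | 1) term
        new = [r0_new]
        for d in range(1, k + 1):
            cur = (((r[d] << _ONE) | _ONE) & col_mask) | carry
            carry = (r[d] << _ONE) | _ONE
            new.append(cur)
        for d in range(k + 1):
            r[d] = new[d]
        found |= (r[k] & goal) != 0
    return found


def bitap_count(
    pattern: JunctionPattern,
    reads: list[str] | np.ndarray,
    search_both_strands: bool = True,
) -> int:
    """Number of reads containing the pattern within its mismatch budget.

    *reads* may be raw strings or a pre-encoded matrix from
    :func:`chimerakit.seq.encode_reads`.  Each read counts once even with
    multiple occurrences; with *search_both_strands* the reverse complement
    of the pattern is searched too.  N bases mismatch everything.
    """
    enc = reads if isinstance(reads, np.ndarray) else encode_reads(list(reads))
    hit = _bitap_match_many(pattern.pattern, enc, pattern.max_mismatches)
    if search_both_strands:
        hit |= _bitap_match_many(revcomp(pattern.pattern), enc, pattern.max_mismatches)
    return int(hit.sum())


# ---------------------------------------------------------------------------
# Support matrix
# ---------------------------------------------------------------------------

@dataclass
class SupportMatrix:
    """Per-chimera x per-sample junction-read counts plus library sizes."""

    counts: pd.DataFrame  # rows chimera_id, columns sample_id, int
    library_sizes: pd.Series  # per sample total read count

    def cpm(self) -> pd.DataFrame:
        """Counts per million library reads."""
        lib = self.library_sizes.reindex(self.counts.columns)
        return self.counts * 1e6 / lib

    def write(self, counts_path: str | Path, libsize_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="chimera_id")
        self.library_sizes.rename("library_size").to_csv(
            libsize_path, sep="\t", index_label="sample_id"
        )


def read_fastq_sequences(path: str | Path) -> list[str]:
    """All read sequences of a (possibly gzipped) FASTQ file, uppercased."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"FASTQ not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [seq.upper() for _, seq, _ in FastqGeneralIterator(fh)]


def count_matrix(
    patterns: list[JunctionPattern],
    sample_fastqs: dict[str, str | Path],
    search_both_strands: bool = True,
) -> SupportMatrix:
    """bitap_count for every (pattern, sample); deterministic by construction."""
    samples = list(sample_fastqs)
    counts = np.zeros((len(patterns), len(samples)), dtype=int)
    lib = {}
    for sj, sample in enumerate(samples):
        try:
            reads = read_fastq_sequences(sample_fastqs[sample])
        except OSError as exc:
            raise OSError(f"sample {sample}: {exc}") from exc
        lib[sample] = len(reads)
        enc = encode_reads(reads)
        for pi, pat in enumerate(patterns):
            counts[pi, sj] = bitap_count(pat, enc, search_both_strands)
    frame = pd.DataFrame(counts, index=[p.chimera_id for p in patterns], columns=samples)
    return SupportMatrix(frame, pd.Series(lib))


# ---------------------------------------------------------------------------
# Paired differential support
# ---------------------------------------------------------------------------

def differential_support(
    matrix: SupportMatrix,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Tumor-vs-normal differential junction support across sample pairs.

    *pairs* lists (tumor_sample, normal_sample) ids; at least 6 complete
    pairs are required for the signed-rank test to be meaningful.  Counts are
    CPM-normalised before testing; p-values are Benjamini-Hochberg adjusted
    across chimeras and the direction is the sign of the median paired
    difference.  *method* is one of ``wilcoxon``, ``sign``, ``ttest``.
    """
    have = set(matrix.counts.columns)
    pairs = [(t, n) for t, n in pairs if t in have and n in have]
    if not pairs:
        raise AnalysisError("no complete tumor/normal pairs in the support matrix")
    if len(pairs) < 6:
        raise AnalysisError(f"only {len(pairs)} complete pairs; >= 6 required")
    cpm = matrix.cpm()
    tumor = cpm[[t for t, _ in pairs]].to_numpy(dtype=float)
    normal = cpm[[n for _, n in pairs]].to_numpy(dtype=float)
    rows = []
    for i, chim in enumerate(cpm.index):
        t, n = tumor[i], normal[i]
        stat, p = _paired_test(t, n, method)
        med = float(np.median(t - n))
        rows.append(
            {
                "chimera_id": chim,
                "statistic": stat,
                "p_value": p,
                "median_diff_cpm": med,
                "direction": "up-in-tumor" if med > 0 else ("down-in-tumor" if med < 0 else "none"),
            }
        )
    cols = ["chimera_id", "statistic", "p_value", "median_diff_cpm", "direction",
            "q_value", "significant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < alpha
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)[cols]


def _paired_test(t: np.ndarray, n: np.ndarray, method: str) -> tuple[float, float]:
    diff = t - n
    if method == "wilcoxon":
        if np.all(diff == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(t, n, zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    if method == "sign":
        nz = diff[diff != 0]
        if len(nz) == 0:
            return 0.0, 1.0
        pos = int(np.sum(nz > 0))
        res = stats.binomtest(pos, len(nz), 0.5)
        return float(pos), float(res.pvalue)
    if method == "ttest":
        if np.all(diff == diff[0]):
            return 0.0, 1.0 if diff[0] == 0 else 0.0
        res = stats.ttest_rel(t, n)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown paired test method {method!r}")
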