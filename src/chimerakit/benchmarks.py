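"""Validation benchmarks: seeded scenarios that measure the pipeline's
headline properties on synthetic cohorts with known ground truth.

Each function generates its own inputs from a seed, runs the relevant
pipeline stage(s) and returns measured quantities (agreement fractions,
sensitivities, calibration rates).  They back both the acceptance test
suite and ``scripts/acceptance.py``.

Problem sizes are chosen to finish on one CPU in a few minutes while
keeping every estimate's Monte-Carlo error well below the margins being
checked; docs/methods.md lists the sizes.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import longread as lr
from . import quantify as qt
from .catalog import ChimeraCandidate, Partner, classify_genomic, classify_junction
from .filters import filter_alignment_uniqueness, filter_mm, filter_recurrence, flag_utr3_breakpoints
from .longread import edit_distance_search
from .quantify import JunctionPattern, bitap_count
from .synthetic import (
    FusionSpec,
    SimulationConfig,
    plant_chimeras,
    simulate_genome_and_annotation,
    simulate_long_reads,
    simulate_short_reads,
    simulate_survival,
)

JUNCTION_CLASSES = ("E/E", "E/M", "M/E", "M/M")
GENOMIC_CLASSES = ("read-through", "intra-chromosomal", "inter-chromosomal")


def _random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------------------
# Matcher-oracle equivalence
# ---------------------------------------------------------------------------

def _hamming_scan(pattern: str, text: str, k: int) -> bool:
    """Brute-force sliding-window oracle; non-ACGT text mismatches everything."""
    m = len(pattern)
    for s in range(len(text) - m + 1):
        d = 0
        for a, b in zip(pattern, text[s : s + m]):
            if a != b or b not in "ACGT":
                d += 1
                if d > k:
                    break
        else:
            return True
    return False


def bitap_oracle_benchmark(seed: int, n_cases: int = 1000) -> dict:
    """Fraction of randomized cases where bitap agrees with the brute scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        m = int(rng.integers(20, 65))
        k = int(rng.integers(0, 4))
        pattern = _random_dna(rng, m)
        read = _random_dna(rng, int(rng.integers(m, 161)), "ACGTN")
        if rng.random() < 0.5:
            copy = list(pattern)
            for _ in range(int(rng.integers(0, 5))):
                copy[int(rng.integers(m))] = "ACGT"[int(rng.integers(4))]
            s = int(rng.integers(0, len(read) - m + 1))
            read = read[:s] + "".join(copy) + read[s + m :]
        jp = JunctionPattern("bench", pattern, m // 2, min(k, (m // 2) // 5))
        got = bitap_count(jp, [read], search_both_strands=False) == 1
        agree += got == _hamming_scan(pattern, read, jp.max_mismatches)
    return {"agreement": agree / n_cases, "n": n_cases}


def _unbanded_dp(pattern: str, read: str) -> int:
    m, n = len(pattern), len(read)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (pattern[i - 1] != read[j - 1]))
        prev = cur
    return min(prev)


def edit_oracle_benchmark(seed: int, n_cases: int = 500) -> dict:
    """Semi-global DP vs an independent unbanded quadratic oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        pat = _random_dna(rng, int(rng.integers(40, 81)))
        core = list(pat)
        for _ in range(int(rng.integers(0, 4))):
            op, p = int(rng.integers(3)), int(rng.integers(len(core)))
            if op == 0:
                core[p] = "ACGT"[int(rng.integers(4))]
            elif op == 1 and len(core) > 1:
                core.pop(p)
            else:
                core.insert(p, "ACGT"[int(rng.integers(4))])
        read = _random_dna(rng, int(rng.integers(0, 60))) + "".join(core) + \
            _random_dna(rng, int(rng.integers(0, 60)))
        hit = edit_distance_search(pat, read, max_edit=len(pat))
        agree += hit.distance == _unbanded_dp(pat, read)
    return {"agreement": agree / n_cases, "n": n_cases}


# ---------------------------------------------------------------------------
# Classification truth recovery
# ---------------------------------------------------------------------------

def classification_benchmark(seed: int, n_per_combo: int = 20) -> dict:
    """Label agreement with planted truth over every class combination."""
    fusions = [
        FusionSpec(jc, gc, 3)
        for jc in JUNCTION_CLASSES
        for gc in GENOMIC_CLASSES
        for _ in range(n_per_combo)
    ]
    cfg = SimulationConfig(
        seed=seed, n_patients=4, contig_lengths=(330_000, 330_000),
        genes_per_contig=110, fusions=fusions, n_decoys=0,
    )
    genome, index = simulate_genome_and_annotation(cfg)
    truth = plant_chimeras(cfg, index, genome)
    jc_ok = gc_ok = 0
    for t in truth:
        cand = ChimeraCandidate(
            five=Partner(t.gene_5p, t.contig_5p, t.strand_5p, t.breakpoint_5p),
            three=Partner(t.gene_3p, t.contig_3p, t.strand_3p, t.breakpoint_3p),
            junction_seq=t.transcript[t.junction_offset - 25 : t.junction_offset + 25],
            sample_id="P001_T",
        )
        jc_ok += classify_junction(cand, index) == t.junction_class
        gc_ok += classify_genomic(cand, index) == t.genomic_class
    n = len(truth)
    return {
        "junction_accuracy": jc_ok / n,
        "genomic_accuracy": gc_ok / n,
        "n": n,
    }


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def filter_benchmark(seed: int) -> dict:
    """Exactness of every cascade stage on a planted cohort with decoys."""
    fusions = (
        [FusionSpec("M/M", gc, 6) for gc in GENOMIC_CLASSES for _ in range(4)]
        + [FusionSpec("E/E", "read-through", 5), FusionSpec("E/E", "read-through", 4),
           FusionSpec("E/M", "intra-chromosomal", 5), FusionSpec("M/E", "inter-chromosomal", 4)]
        + [FusionSpec("E/E", "inter-chromosomal", 6) for _ in range(6)]
        + [FusionSpec("E/M", gc, 6, in_utr3=True) for gc in GENOMIC_CLASSES]
    )
    cfg = SimulationConfig(
        seed=seed, n_patients=10, contig_lengths=(220_000, 220_000),
        genes_per_contig=40, fusions=fusions, n_decoys=10,
    )
    genome, index = simulate_genome_and_annotation(cfg)
    truth = plant_chimeras(cfg, index, genome)
    from .synthetic import candidate_table, make_decoy_candidates
    decoys = make_decoy_candidates(
        cfg, index, genome, exclude_pairs={(t.gene_5p, t.gene_3p) for t in truth}
    )
    table = pd.concat(
        [candidate_table(cfg, truth), decoys.drop(columns=["decoy_id"])],
        ignore_index=True,
    )
    with tempfile.TemporaryDirectory() as td:
        path = Path(td) / "cands.tsv"
        table.to_csv(path, sep="\t", index=False)
        from .catalog import classify_all, parse_candidates
        cands, _ = parse_candidates(path, index)
        cands = classify_all(cands, index)

    tmap = {t.chimera_id: t for t in truth}
    decoy_ids = set(decoys["decoy_id"])
    conserved = True

    s1, r1 = filter_mm(cands)
    conserved &= r1.n_in == r1.n_removed + r1.n_out
    mm_exact = (
        all(tmap[c.chimera_id].junction_class == "M/M"
            for c in cands if c not in s1 and c.chimera_id in tmap)
        and all(c.junction_class != "M/M" for c in s1)
        and r1.n_removed == sum(1 for c in cands if c.junction_class == "M/M")
    )

    s2, r2 = filter_recurrence(s1, min_patients=5)
    conserved &= r2.n_in == r2.n_removed + r2.n_out
    ids2 = {c.chimera_id for c in s2}
    rec_exact = all(
        (t.chimera_id in ids2) == (len(t.carriers) >= 5)
        for t in truth if t.junction_class != "M/M"
    )

    s3, r3 = filter_alignment_uniqueness(s2, genome)
    conserved &= r3.n_in == r3.n_removed + r3.n_out
    ids3 = {c.chimera_id for c in s3}
    decoys_in2 = {c.chimera_id for c in s2} & decoy_ids
    decoy_removal = 1.0 - (len(ids3 & decoy_ids) / len(decoys_in2)) if decoys_in2 else 1.0
    true_retention = (
        len(ids3 & (ids2 & set(tmap))) / len(ids2 & set(tmap)) if ids2 & set(tmap) else 1.0
    )

    s4, flagged, r4 = flag_utr3_breakpoints(s3, index)
    conserved &= r4.n_in == r4.n_removed + r4.n_out
    flagged_ids = {c.chimera_id for c in flagged}
    expected_flagged = {t.chimera_id for t in truth if t.in_utr3 and t.chimera_id in ids3}
    utr_exact = flagged_ids == expected_flagged

    return {
        "mm_exact": float(mm_exact),
        "recurrence_exact": float(rec_exact),
        "decoy_removal": decoy_removal,
        "true_retention": true_retention,
        "utr3_exact": float(utr_exact),
        "conservation": float(conserved),
        "n": len(cands),
    }


# ---------------------------------------------------------------------------
# Quantification recovery + paired differential support
# ---------------------------------------------------------------------------

def quantification_benchmark(
    seed: int, n_null: int = 200, n_pairs: int = 30
) -> dict:
    """Error-free exact count recovery and differential discovery with FDP.

    One chimera is planted at a 4x tumor/normal junction-read rate across
    all *n_pairs* patients; *n_null* chimeras have ratio 1.  Reads are
    error-free and matching is exact (k=0), so every support-matrix cell
    must equal the generator's own junction-spanning tally.
    """
    fusions = [FusionSpec("E/E", "read-through", n_pairs, 4.0)] + [
        FusionSpec("E/M", ("intra-chromosomal", "inter-chromosomal")[i % 2], n_pairs, 1.0)
        for i in range(n_null)
    ]
    cfg = SimulationConfig(
        seed=seed, n_patients=n_pairs, contig_lengths=(220_000, 220_000),
        genes_per_contig=36, fusions=fusions, n_decoys=0,
        short_error_rate=0.0, parental_coverage=0.5, chimeric_coverage=3.0,
    )
    genome, index = simulate_genome_and_annotation(cfg)
    truth = plant_chimeras(cfg, index, genome)
    with tempfile.TemporaryDirectory() as td:
        paths = simulate_short_reads(cfg, index, genome, truth, td)
        patterns = [
            JunctionPattern(
                t.chimera_id,
                t.transcript[t.junction_offset - 20 : t.junction_offset + 20],
                20, 0,
            )
            for t in truth
        ]
        matrix = qt.count_matrix(patterns, paths)
    cells = exact = 0
    for t in truth:
        for s in matrix.counts.columns:
            cells += 1
            exact += matrix.counts.loc[t.chimera_id, s] == t.short_counts.get(s, 0)
    pairs = [(f"{p}_T", f"{p}_N") for p in cfg.patients]
    diff = qt.differential_support(matrix, pairs).set_index("chimera_id")
    planted = truth[0].chimera_id
    discoveries = set(diff.index[diff["significant"]])
    null_ids = {t.chimera_id for t in truth[1:]}
    fdp = len(discoveries & null_ids) / max(len(discoveries), 1)
    return {
        "cell_agreement": exact / cells,
        "n_cells": cells,
        "planted_q": float(diff.loc[planted, "q_value"]),
        "planted_direction": str(diff.loc[planted, "direction"]),
        "null_fdp": fdp,
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# Long-read validation
# ---------------------------------------------------------------------------

def longread_benchmark(seed: int, n_chimeras: int = 24) -> dict:
    """Chimera-level sensitivity at 8% read error plus decoy specificity."""
    fusions = [
        FusionSpec(JUNCTION_CLASSES[i % 4], GENOMIC_CLASSES[i % 3], 4)
        for i in range(n_chimeras)
    ]
    cfg = SimulationConfig(
        seed=seed, n_patients=6, contig_lengths=(220_000, 220_000),
        genes_per_contig=36, fusions=fusions, n_decoys=0,
        long_error_rate=0.08,
    )
    genome, index = simulate_genome_and_annotation(cfg)
    truth = plant_chimeras(cfg, index, genome)
    min_anchor = 20
    with tempfile.TemporaryDirectory() as td:
        paths = simulate_long_reads(cfg, index, genome, truth, td)
        patterns = {
            t.chimera_id: t.transcript[t.junction_offset - 30 : t.junction_offset + 30]
            for t in truth
        }
        support = lr.call_long_read_support(patterns, paths, min_flank_anchor=min_anchor)
        from .synthetic import audit_junction_margins
        margins = {s: audit_junction_margins(p) for s, p in paths.items()}
        # swapped-flank decoy reads: both flanks present, wrong order
        rng = np.random.default_rng(seed + 1)
        decoy_dir = Path(td) / "decoy"
        decoy_dir.mkdir()
        with open(decoy_dir / "D1.long.fastq", "w") as fh:
            for i, (cid, pat) in enumerate(patterns.items()):
                read = (_random_dna(rng, 150) + pat[30:] + pat[:30] + _random_dna(rng, 150))
                fh.write(f"@decoy{i}\n{read}\n+\n{'I' * len(read)}\n")
        decoy_support = lr.call_long_read_support(
            patterns, {"D1": decoy_dir / "D1.long.fastq"}
        )
    detected = {s.chimera_id for s in support}
    with_reads = [t for t in truth if sum(t.long_counts.values()) > 0]
    sens = sum(t.chimera_id in detected for t in with_reads) / len(with_reads)
    # a call is false only if no planted read in that sample even reached the
    # anchoring margin the caller requires
    false_calls = sum(
        1 for s in support
        if margins.get(s.sample_id, {}).get(s.chimera_id, 0) < min_anchor
    )
    return {
        "sensitivity": sens,
        "n_chimeras": len(with_reads),
        "false_sample_calls": false_calls,
        "decoy_support_calls": len(decoy_support),
        "n_decoy_reads": len(patterns),
    }


# ---------------------------------------------------------------------------
# Survival calibration
# ---------------------------------------------------------------------------

def _one_cohort_pvalue(
    n: int, beta: float, rng: np.random.Generator, split_quantile: float = 0.875
) -> float:
    burden = rng.poisson(8.0, n).astype(float)
    time, event = simulate_survival(burden, 0.01, beta, 0.3, rng)
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "tumor_sample_id": [f"P{i}_T" for i in range(n)],
            "normal_sample_id": [f"P{i}_N" for i in range(n)],
            "bcr_time": time,
            "bcr_event": event,
            "gleason": np.full(n, 7),
        }
    )
    b = pd.Series(burden, index=clinical["patient_id"])
    out = clin.km_logrank_split(b, clinical, split_quantile)
    return out["p_value"]


def survival_benchmark(
    seed: int, n_null: int = 1000, n_power: int = 300, n_patients: int = 200
) -> dict:
    """Log-rank type-I error at beta=0 and power at beta=log 3 (n=200)."""
    rng = np.random.default_rng(seed)
    null_rej = 0
    for _ in range(n_null):
        try:
            null_rej += _one_cohort_pvalue(n_patients, 0.0, rng) < 0.05
        except Exception:
            pass  # degenerate split; does not count as rejection
    power_rej = 0
    for _ in range(n_power):
        power_rej += _one_cohort_pvalue(n_patients, math.log(3.0), rng) < 0.05
    # KM vs empirical survival on one uncensored sample
    times = rng.exponential(10.0, 300)
    curve = clin.km_curve(times, np.ones(300, dtype=int))
    km_dev = max(
        abs(row["survival"] - np.mean(times > row["time"]))
        for _, row in curve.iterrows()
    )
    # split sizes on a tie-free burden
    n = n_patients
    burden = pd.Series(
        np.arange(n, dtype=float),
        index=[f"P{i}" for i in range(n)],
    )
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "tumor_sample_id": [f"P{i}_T" for i in range(n)],
            "normal_sample_id": [f"P{i}_N" for i in range(n)],
            "bcr_time": rng.exponential(50, n),
            "bcr_event": np.ones(n, dtype=int),
            "gleason": np.full(n, 7),
        }
    )
    split = clin.km_logrank_split(burden, clinical, 0.875)
    return {
        "type1_rate": null_rej / n_null,
        "n_null_cohorts": n_null,
        "power": power_rej / n_power,
        "n_power_cohorts": n_power,
        "km_max_abs_deviation": km_dev,
        "n_high": split["n_high"],
        "n_low": split["n_low"],
        "expected_high": int(np.ceil(0.125 * n)),
    }


# ---------------------------------------------------------------------------
# End-to-end determinism
# ---------------------------------------------------------------------------

def determinism_benchmark(seed: int) -> dict:
    """Two run-all executions under one seed must be byte-identical."""
    from .cli import PipelineConfig, run_all

    cfg = PipelineConfig(seed=seed)
    cfg.sim = {
        "n_patients": 8,
        "genes_per_contig": 12,
        "contig_lengths": [100_000, 100_000],
        "fusions": [
            {"junction_class": "E/E", "genomic_class": "read-through",
             "n_patients": 8, "tumor_normal_ratio": 4.0},
            {"junction_class": "M/M", "genomic_class": "intra-chromosomal", "n_patients": 5},
            {"junction_class": "M/E", "genomic_class": "inter-chromosomal", "n_patients": 6},
            {"junction_class": "E/M", "genomic_class": "read-through",
             "n_patients": 5, "in_utr3": True},
        ],
        "n_decoys": 1,
    }
    with tempfile.TemporaryDirectory() as td:
        a, b = Path(td) / "a", Path(td) / "b"
        run_all(cfg, a)
        run_all(cfg, b)
        rels_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        rels_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        identical = rels_a == rels_b and all(
            (a / r).read_bytes() == (b / r).read_bytes() for r in rels_a
        )
    return {"identical": float(identical), "n_files": len(rels_a)}
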