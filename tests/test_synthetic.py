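"""Generator contracts: determinism, planting rules, read and cohort models."""

import numpy as np
import pytest

from chimerakit.errors import ConfigError, PlantingError
from chimerakit.synthetic import (
    FusionSpec,
    SimulationConfig,
    audit_span_counts,
    plant_chimeras,
    simulate_all,
    simulate_cohort,
    simulate_genome_and_annotation,
    simulate_short_reads,
    simulate_survival,
    true_burden,
)
from tests.conftest import small_config


class TestGenomeAnnotation:
    def test_containment_and_counts(self):
        cfg = SimulationConfig(seed=5, contig_lengths=(60_000,), genes_per_contig=10,
                               fusions=[], n_decoys=0)
        genome, index = simulate_genome_and_annotation(cfg)
        assert len(index) == 10
        for g in index.genes.values():
            assert 0 <= g.span[0] < g.span[1] <= 60_000
            assert g.utr3 and g.cds

    def test_deterministic_bytes(self, tmp_path):
        cfg = small_config()
        a = simulate_all(cfg, tmp_path / "a")
        b = simulate_all(cfg, tmp_path / "b")
        for name in ("genome.fa", "annotation.gtf", "candidates.tsv", "clinical.tsv",
                     "truth_chimeras.tsv", "truth_counts.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        for s in a.short_fastqs:
            assert a.short_fastqs[s].read_bytes() == b.short_fastqs[s].read_bytes()
        for s in a.long_fastqs:
            assert a.long_fastqs[s].read_bytes() == b.long_fastqs[s].read_bytes()

    def test_zero_genes_gives_empty_annotation(self):
        cfg = SimulationConfig(seed=5, contig_lengths=(10_000,), genes_per_contig=0,
                               fusions=[], n_decoys=0)
        genome, index = simulate_genome_and_annotation(cfg)
        assert len(index) == 0 and len(genome["chr1"]) == 10_000

    def test_infeasible_config_rejected(self):
        cfg = SimulationConfig(seed=5, contig_lengths=(5_000,), genes_per_contig=10,
                               fusions=[], n_decoys=0)
        with pytest.raises(ConfigError, match="cannot fit"):
            simulate_genome_and_annotation(cfg)

    def test_same_strand_neighbors_exist(self):
        cfg = SimulationConfig(seed=6, fusions=[], n_decoys=0)
        _, index = simulate_genome_and_annotation(cfg)
        found = False
        for contig in ("chr1", "chr2"):
            gs = index.genes_on(contig)
            found |= any(a.strand == b.strand for a, b in zip(gs, gs[1:]))
        assert found


class TestPlanting:
    def test_breakpoint_classes_by_construction(self):
        cfg = small_config(seed=77)
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        assert len(truth) == len(cfg.fusions)
        for t in truth:
            g5, g3 = index.get(t.gene_5p), index.get(t.gene_3p)
            e5 = t.breakpoint_5p + 1 if g5.strand == "+" else t.breakpoint_5p
            e3 = t.breakpoint_3p if g3.strand == "+" else t.breakpoint_3p + 1
            jc5, jc3 = t.junction_class.split("/")
            assert (e5 in g5.boundaries) == (jc5 == "E")
            assert (e3 in g3.boundaries) == (jc3 == "E")
            if t.genomic_class == "inter-chromosomal":
                assert g5.contig != g3.contig
            else:
                assert g5.contig == g3.contig
            if t.in_utr3:
                assert g3.in_utr3(t.breakpoint_3p)

    def test_transcript_joins_spliced_segments(self):
        cfg = small_config(seed=78)
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        for t in truth[:3]:
            g5, g3 = index.get(t.gene_5p), index.get(t.gene_3p)
            t5, t3 = g5.spliced_sequence(genome), g3.spliced_sequence(genome)
            j = t.junction_offset
            assert t.transcript[:j] == t5[:j]
            assert t.transcript[j:] == t3[len(t3) - (len(t.transcript) - j):]

    def test_inter_with_one_contig_impossible(self):
        cfg = SimulationConfig(
            seed=5, contig_lengths=(100_000,), genes_per_contig=10,
            fusions=[FusionSpec("E/E", "inter-chromosomal", 2)], n_patients=4, n_decoys=0,
        )
        genome, index = simulate_genome_and_annotation(cfg)
        with pytest.raises(PlantingError, match="inter"):
            plant_chimeras(cfg, index, genome)

    def test_recurrence_above_cohort_rejected(self):
        with pytest.raises(ConfigError, match="recurrence"):
            SimulationConfig(n_patients=4, fusions=[FusionSpec("E/E", "read-through", 5)])


class TestShortReads:
    def test_zero_error_reads_are_exact_substrings(self, tmp_path):
        cfg = small_config(seed=90, short_error_rate=0.0, n_patients=3,
                           fusions=[FusionSpec("E/E", "read-through", 3)], n_decoys=0)
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        paths = simulate_short_reads(cfg, index, genome, truth, tmp_path)
        transcripts = {g.gene_id: g.spliced_sequence(genome) for g in index.genes.values()}
        transcripts.update({t.chimera_id: t.transcript for t in truth})
        from chimerakit.seq import revcomp
        checked = 0
        for path in paths.values():
            with open(path) as fh:
                lines = fh.read().splitlines()
            for name, seq in zip(lines[::4], lines[1::4]):
                src = name.split("|src=")[1].split("|")[0]
                assert seq in transcripts[src] or revcomp(seq) in transcripts[src]
                checked += 1
        assert checked > 100

    def test_poisson_read_count(self, tmp_path):
        """Expected read count ~= coverage * L / r, within 5 SD."""
        cfg = SimulationConfig(
            seed=91, contig_lengths=(80_000,), genes_per_contig=10, n_patients=1,
            fusions=[], n_decoys=0, parental_coverage=3.0,
        )
        genome, index = simulate_genome_and_annotation(cfg)
        paths = simulate_short_reads(cfg, index, genome, [], tmp_path)
        expected = sum(
            3.0 * g.spliced_length() / cfg.short_read_length for g in index.genes.values()
        )
        for path in paths.values():
            n = sum(1 for _ in open(path)) / 4
            assert abs(n - expected) < 5 * np.sqrt(expected)

    def test_truth_counts_match_read_name_audit(self, sim_result):
        tmap = {t.chimera_id: t for t in sim_result.truth}
        for sample, path in sim_result.short_fastqs.items():
            audit = audit_span_counts(path)
            for cid, t in tmap.items():
                assert audit.get(cid, 0) == t.short_counts.get(sample, 0)

    def test_null_ratio_paired_counts_symmetric(self):
        """ratio 1 => tumor-minus-normal junction counts centred on zero."""
        cfg = small_config(
            seed=92, n_patients=20,
            fusions=[FusionSpec("E/E", "read-through", 20, 1.0)], n_decoys=0,
        )
        import tempfile
        from pathlib import Path
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        simulate_short_reads(cfg, index, genome, truth, Path(tempfile.mkdtemp()))
        t = truth[0]
        diffs = [
            t.short_counts.get(f"{p}_T", 0) - t.short_counts.get(f"{p}_N", 0)
            for p in cfg.patients
        ]
        from scipy import stats
        w = stats.wilcoxon(diffs)
        assert w.pvalue > 0.01  # no systematic tumor/normal difference


class TestCohort:
    def test_zero_censoring_all_events(self, rng):
        t, e = simulate_survival(np.zeros(50), 0.01, 0.0, 0.0, rng)
        assert (e == 1).all() and (t > 0).all()

    def test_large_effect_shortens_high_burden_survival(self, rng):
        burden = np.concatenate([np.zeros(500), np.full(500, 3.0)])
        t, _ = simulate_survival(burden, 0.01, np.log(3.0), 0.0, rng)
        assert np.median(t[500:]) < np.median(t[:500]) / 5

    def test_null_beta_independent_of_burden(self, rng):
        from lifelines.statistics import logrank_test
        rejected = 0
        for _ in range(100):
            burden = rng.poisson(8.0, 100).astype(float)
            t, e = simulate_survival(burden, 0.01, 0.0, 0.3, rng)
            hi = burden > np.quantile(burden, 0.875)
            res = logrank_test(t[hi], t[~hi], e[hi], e[~hi])
            rejected += res.p_value < 0.05
        assert rejected <= 12  # ~5% nominal

    def test_gleason_enriched_with_burden(self):
        cfg = small_config(seed=93, n_patients=200, gleason_enrichment=0.5,
                           fusions=[FusionSpec("E/E", "read-through", 100)], n_decoys=0)
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        clin = simulate_cohort(cfg, truth)
        b = true_burden(cfg, truth).reindex(clin["patient_id"]).to_numpy()
        mean_high = clin.loc[b > 0, "gleason"].mean()
        mean_low = clin.loc[b == 0, "gleason"].mean()
        assert mean_high > mean_low

    def test_negative_hazard_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_survival(np.ones(3), 0.0, 0.1, 0.1, rng)
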