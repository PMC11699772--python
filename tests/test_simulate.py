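"""Generator contracts: determinism, placement statistics, truth conservation."""

import numpy as np
import pytest
from scipy import stats

from xciseq import io
from xciseq.errors import ConfigurationError, DataError
from xciseq.pseudogenome import build_pseudogenomes, filter_variants
from xciseq.scenarios import _resolved_table, build_world
from xciseq.simulate import (
    ChromosomeSpec,
    PlantedDomain,
    SimulationConfig,
    XCIProgram,
    simulate_annotation,
    simulate_count_matrix,
    simulate_cutrun,
    simulate_hybrid_reference,
    simulate_rnaseq,
)


def _config(**kw):
    kw.setdefault("seed", 7)
    kw.setdefault("chromosomes", (ChromosomeSpec("chr1", 50_000),))
    return SimulationConfig(**kw)


class TestConfigValidation:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(chromosomes=(ChromosomeSpec("chr1", 0),))

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(chimera_fraction=1.5)


class TestHybridReference:
    def test_zero_density_means_no_variants(self):
        ref, calls = simulate_hybrid_reference(_config(snp_density=0.0))
        assert calls == []
        pair = build_pseudogenomes(ref, filter_variants(calls)[0])
        assert pair.genome_g1 == ref and pair.genome_g2 == ref

    def test_identical_seed_gives_identical_bytes(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = _config()
            ref, calls = simulate_hybrid_reference(cfg)
            fa = tmp_path / f"{run}.fa"
            vcf = tmp_path / f"{run}.vcf"
            io.write_fasta(ref, str(fa))
            io.write_vcf(calls, cfg.chrom_lengths, str(vcf))
            paths.append((fa.read_bytes(), vcf.read_bytes()))
        assert paths[0] == paths[1]

    def test_snp_count_matches_binomial_placement(self):
        # 1 Mb at density 1e-3: expect 1000 +/- 3 binomial sd
        cfg = _config(
            chromosomes=(ChromosomeSpec("chr1", 1_000_000),), snp_density=1e-3
        )
        _, calls = simulate_hybrid_reference(cfg)
        n, p = 1_000_000, 1e-3
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(calls) - n * p) <= 3 * sd

    def test_emitted_fractions(self):
        _, calls = simulate_hybrid_reference(
            _config(chromosomes=(ChromosomeSpec("chr1", 500_000),), snp_density=0.01)
        )
        indel = np.mean([c.is_indel for c in calls])
        lowq = np.mean([c.filter_status != "PASS" for c in calls if c.is_snv])
        assert abs(indel - 0.10) < 0.02
        assert abs(lowq - 0.10) < 0.02


class TestAnnotation:
    def test_zero_genes(self):
        assert simulate_annotation(_config(genes_per_chromosome=0)) == []

    def test_minus_strand_tss_is_rightmost(self):
        genes = simulate_annotation(_config(genes_per_chromosome=10))
        minus = [g for g in genes if g.strand == "-"]
        assert minus
        for g in minus:
            assert g.tss == g.end - 1

    def test_exon_lengths_sum_to_transcript_length(self):
        for g in simulate_annotation(_config(genes_per_chromosome=10)):
            assert sum(e - s for s, e in g.exons) == g.transcript_length

    def test_genes_do_not_overlap(self):
        genes = sorted(
            simulate_annotation(_config(genes_per_chromosome=12)), key=lambda g: g.start
        )
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_too_many_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_annotation(
                _config(chromosomes=(ChromosomeSpec("chr1", 5000),), genes_per_chromosome=10)
            )

    def test_x_genes_get_classes_and_one_xist(self):
        cfg = _config(
            chromosomes=(ChromosomeSpec("chrX", 50_000, is_x=True),),
            genes_per_chromosome=10,
        )
        genes = simulate_annotation(cfg, XCIProgram())
        assert sum(g.is_xist for g in genes) == 1
        assert all(g.silencing_class for g in genes if not g.is_xist)


class TestRnaseq:
    def _world(self, seed=3, **kw):
        cfg = SimulationConfig(
            seed=seed,
            chromosomes=(ChromosomeSpec("chrX", 60_000, is_x=True),),
            genes_per_chromosome=6,
            **kw,
        )
        _, _, snps, _, pair, genes = build_world(cfg)
        return cfg, snps, pair, genes

    def test_zero_xi_fraction_single_haplotype(self):
        cfg, _, pair, genes = self._world()
        resolved = _resolved_table(genes, {g.gene_id: 0.0 for g in genes})
        _, truth = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=2000)
        assert (truth["haplotype"] == 2).all()

    def test_balanced_fraction_within_binomial_bounds(self):
        cfg, _, pair, genes = self._world()
        resolved = _resolved_table(genes, {g.gene_id: 0.5 for g in genes})
        _, truth = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=10_000)
        n = len(truth)
        frac = (truth["haplotype"] == 1).mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_error_free_reads_match_source_haplotype(self):
        cfg, _, pair, genes = self._world(sequencing_error_rate=0.0)
        resolved = _resolved_table(genes, {g.gene_id: 0.4 for g in genes})
        records, truth = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=500)
        hap = dict(zip(truth["read_id"], truth["haplotype"]))
        for rec in records:
            src = pair.genome_g1 if hap[rec.read_id] == 1 else pair.genome_g2
            assert rec.sequence == src[rec.chrom][rec.start : rec.end]

    def test_truth_conservation(self):
        cfg, _, pair, genes = self._world()
        resolved = _resolved_table(genes, {g.gene_id: 0.5 for g in genes})
        records, truth = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=3000)
        assert len(records) == len(truth)
        assert truth["read_id"].is_unique
        assert {r.read_id for r in records} == set(truth["read_id"])

    def test_determinism(self):
        cfg, _, pair, genes = self._world()
        resolved = _resolved_table(genes, {g.gene_id: 0.5 for g in genes})
        a, _ = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=500)
        b, _ = simulate_rnaseq(pair, genes, resolved, cfg, "l", total_reads=500)
        assert a == b

    def test_missing_chromosome_raises(self):
        cfg, _, pair, genes = self._world()
        bad = [
            type(genes[0])(
                gene_id="bad", chrom="chr9", strand="+", exons=((0, 200),)
            )
        ]
        with pytest.raises(DataError):
            simulate_rnaseq(pair, bad, _resolved_table(bad, {}), cfg, "l")


class TestCutrun:
    def _pair(self, cfg):
        ref, calls = simulate_hybrid_reference(cfg)
        return build_pseudogenomes(ref, filter_variants(calls)[0])

    def test_no_chimeras_when_fraction_zero(self):
        cfg = SimulationConfig(
            seed=5,
            chromosomes=(ChromosomeSpec("chr1", 50_000), ChromosomeSpec("chr2", 50_000)),
            chimera_fraction=0.0,
            cutrun_fragments=2000,
        )
        _, truth = simulate_cutrun(self._pair(cfg), cfg, [], "l", with_sequences=False)
        assert not truth["chimeric"].any()

    def test_unenriched_midpoints_are_uniform(self):
        """Enrichment factor 1 leaves the midpoint distribution uniform
        (Kolmogorov-Smirnov at alpha=0.01 over 20 seeds)."""
        n_reject = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                chromosomes=(ChromosomeSpec("chr1", 100_000),),
                heavy_tail_fraction=0.0,
                cutrun_fragments=1500,
            )
            domains = [PlantedDomain("chr1", 20_000, 30_000, 1.0)]
            _, truth = simulate_cutrun(self._pair(cfg), cfg, domains, "l", with_sequences=False)
            mid = (truth["start"] + truth["end"]) / 2
            p = stats.kstest(mid / 100_000, "uniform").pvalue
            n_reject += p < 0.01
        assert n_reject <= 2  # expect 0.2 rejections under uniformity

    def test_mixture_share_of_planted_domain(self):
        # factor 10 over 1% of the genome: share = 10*0.01 / (10*0.01 + 0.99)
        cfg = SimulationConfig(
            seed=11,
            chromosomes=(ChromosomeSpec("chr1", 100_000),),
            cutrun_fragments=8000,
        )
        domains = [PlantedDomain("chr1", 50_000, 51_000, 10.0)]
        _, truth = simulate_cutrun(self._pair(cfg), cfg, domains, "l", with_sequences=False)
        expected = 10 * 0.01 / (10 * 0.01 + 0.99)
        share = (truth["domain"] == 0).mean()
        sd = np.sqrt(expected * (1 - expected) / len(truth))
        assert abs(share - expected) <= 3 * sd

    def test_violation_flags_recorded(self):
        cfg = SimulationConfig(
            seed=2,
            chromosomes=(ChromosomeSpec("chr1", 80_000), ChromosomeSpec("chr2", 80_000)),
            cutrun_fragments=4000,
        )
        pairs, truth = simulate_cutrun(self._pair(cfg), cfg, [], "l", with_sequences=False)
        assert len(pairs) == len(truth)
        assert truth["chimeric"].mean() == pytest.approx(0.01, abs=0.01)
        assert truth["overlong"].mean() == pytest.approx(0.02, abs=0.01)
        for (r1, r2), chim in zip(pairs, truth["chimeric"]):
            assert (r1.chrom != r2.chrom) == chim

    def test_subunit_enrichment_rejected(self):
        cfg = SimulationConfig(seed=1, chromosomes=(ChromosomeSpec("chr1", 10_000),))
        with pytest.raises(ConfigurationError):
            simulate_cutrun(
                self._pair(cfg), cfg, [PlantedDomain("chr1", 0, 100, 0.5)], "l"
            )

    def test_domain_outside_chromosome_rejected(self):
        cfg = SimulationConfig(seed=1, chromosomes=(ChromosomeSpec("chr1", 10_000),))
        with pytest.raises(DataError):
            simulate_cutrun(
                self._pair(cfg), cfg, [PlantedDomain("chr1", 5_000, 20_000, 2.0)], "l"
            )


class TestCountMatrix:
    def test_determinism_and_shapes(self):
        a, truth_a, groups = simulate_count_matrix(9, n_genes=50)
        b, truth_b, _ = simulate_count_matrix(9, n_genes=50)
        assert a.equals(b) and truth_a.equals(truth_b)
        assert a.shape == (50, 6)
        assert set(groups.values()) == {"ref", "test"}

    def test_planted_fold_moves_means(self):
        counts, truth, groups = simulate_count_matrix(
            4, n_genes=300, de_fraction=0.2, de_log2_fold=2.0
        )
        test_libs = [l for l, g in groups.items() if g == "test"]
        ref_libs = [l for l, g in groups.items() if g == "ref"]
        lfc = np.log2(counts[test_libs].mean(axis=1) + 1) - np.log2(
            counts[ref_libs].mean(axis=1) + 1
        )
        assert lfc[truth].abs().mean() > 1.0
        assert lfc[~truth].abs().mean() < 0.5
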