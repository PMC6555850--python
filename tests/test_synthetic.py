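"""Synthetic-data generator: determinism, planted truth, round-trips."""

import dataclasses
import filecmp

import numpy as np
import pytest

from regscore import motifs as mo
from regscore.expression import ExpressionTable
from regscore.genomics import call_enriched_peaks, read_bed, read_gene_annotation
from regscore.synthetic import (
    ConfigurationError,
    SimulationConfig,
    SyntheticTruth,
    decode,
    generate_expression,
    generate_genome,
    generate_peaks_and_motifs,
    simulate,
    simulate_promoter_hits,
)

RC = str.maketrans("ACGT", "TGCA")


def small(**kw) -> SimulationConfig:
    base = dict(n_genes=25, n_enriched_genes=15, n_tfs=4,
                chrom_length=250_000, distal_max_bp=35_000,
                min_gene_spacing=7_000, seed=2)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_chromosome_too_small(self):
        with pytest.raises(ConfigurationError, match="too small"):
            generate_genome(small(n_genes=2, n_enriched_genes=2,
                                  chrom_length=75_000))

    def test_probability_out_of_range(self):
        with pytest.raises(ConfigurationError, match="\\[0, 1\\]"):
            generate_genome(small(promoter_dhs_prob=1.5))

    def test_coefficient_length_mismatch(self):
        with pytest.raises(ConfigurationError, match="true_coefficients"):
            small(true_coefficients=[1.0, 2.0]).validate()

    def test_unknown_scheme(self):
        with pytest.raises(ConfigurationError, match="generating_scheme"):
            small(generating_scheme="distal_only").validate()


class TestGenerateGenome:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        a = simulate(small(), tmp_path / "a")
        b = simulate(small(), tmp_path / "b")
        for name in ("genome.fa", "genes.tsv", "target.bed", "ref1.bed",
                     "expression.tsv", "pwms.jaspar", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_base_composition_near_uniform(self):
        cfg = SimulationConfig(n_genes=200, chrom_length=5_000_000, seed=7,
                               n_enriched_genes=100)
        genome, genes = generate_genome(cfg)
        freqs = np.bincount(genome, minlength=4) / len(genome)
        assert np.all(np.abs(freqs - 0.25) < 0.01)
        assert len({g.tss for g in genes}) == 200

    def test_tss_margins_leave_distal_window(self):
        cfg = small()
        _, genes = generate_genome(cfg)
        for g in genes:
            assert cfg.distal_max_bp <= g.tss <= cfg.chrom_length - cfg.distal_max_bp


class TestPeaksAndMotifs:
    def test_promoter_prob_one_covers_every_gene(self):
        cfg = small(promoter_dhs_prob=1.0)
        genome, genes = generate_genome(cfg)
        target, _, _, truth, _ = generate_peaks_and_motifs(cfg, genes, genome)
        for g in genes:
            assert any(
                p.start < g.tss + 3000 and g.tss - 3000 < p.end for p in target
            ), g.gene_id
            assert g.gene_id in truth.promoter_peak_of_gene

    def test_plant_prob_zero_gives_no_sites(self):
        cfg = small(motif_plant_prob=0.0)
        genome, genes = generate_genome(cfg)
        _, _, _, truth, planted = generate_peaks_and_motifs(cfg, genes, genome)
        assert truth.planted_sites == {}
        assert np.array_equal(planted, genome)

    def test_planted_sites_match_consensus_in_genome(self):
        cfg = small(motif_plant_prob=0.4)
        genome, genes = generate_genome(cfg)
        target, _, pwms, truth, planted = generate_peaks_and_motifs(
            cfg, genes, genome)
        consensus = {p.tf_name: p.consensus for p in pwms}
        by_name = {p.name: p for p in target}
        n_sites = 0
        for (tf, peak_name), sites in truth.planted_sites.items():
            peak = by_name[peak_name]
            for offset, strand in sites:
                n_sites += 1
                assert 0 <= offset <= peak.width - cfg.motif_length
                seq = decode(planted[peak.start + offset:
                                     peak.start + offset + cfg.motif_length])
                want = consensus[tf]
                if strand == "-":
                    want = want.translate(RC)[::-1]
                assert seq == want
        assert n_sites > 0

    def test_planting_conserves_genome_match_count(self):
        # consensus occurrences added to the genome == sites recorded
        cfg = small(motif_plant_prob=0.35, seed=9)
        genome, genes = generate_genome(cfg)
        _, _, pwms, truth, planted = generate_peaks_and_motifs(cfg, genes, genome)
        before, after = decode(genome), decode(planted)

        def count(hay, needle):
            n = start = 0
            while (i := hay.find(needle, start)) != -1:
                n, start = n + 1, i + 1
            return n

        for pwm in pwms:
            cons = pwm.consensus
            rc = cons.translate(RC)[::-1]
            recorded = sum(
                sum(1 for _ in sites)
                for (tf, _), sites in truth.planted_sites.items() if tf == pwm.tf_name
            )
            added = (count(after, cons) + count(after, rc)) - (
                count(before, cons) + count(before, rc))
            # planting another TF's site can overwrite a spurious match,
            # so allow the count to come out within the recorded number
            assert added <= recorded
            assert added >= recorded - 2

    def test_shared_fraction_zero_means_all_peaks_enriched(self):
        cfg = small(shared_fraction=0.0)
        genome, genes = generate_genome(cfg)
        target, refs, _, truth, _ = generate_peaks_and_motifs(cfg, genes, genome)
        enriched = call_enriched_peaks(target, refs)
        assert len(enriched) == len(target)
        assert len(truth.enriched_dhs_names) == len(target)

    def test_peaks_disjoint_within_set(self, sim_result):
        for ps in [sim_result.target, *sim_result.references]:
            for a, b in zip(ps.peaks, ps.peaks[1:]):
                assert a.chrom != b.chrom or a.end <= b.start


class TestGenerateExpression:
    def test_zero_noise_round_trips_through_files(self, tmp_path):
        cfg = small(noise_sd=0.0, replicate_jitter_sd=0.0,
                    true_coefficients=[0.8, 0.0, 1.2, 0.5])
        res = simulate(cfg, tmp_path)
        table = ExpressionTable.read_tsv(tmp_path / "expression.tsv")
        truth = SyntheticTruth.from_json(tmp_path / "truth.json")
        for rep in (1, 2):
            y = np.log2(table.values[f"target.rep{rep}"].values + 1.0)
            want = truth.beta0 + truth.gene_tfrs_features @ truth.beta
            np.testing.assert_allclose(y, want, atol=1e-6)

    def test_dimension_mismatch_errors(self):
        cfg = small()
        genome, genes = generate_genome(cfg)
        truth = SyntheticTruth(generating_scheme="pval")
        with pytest.raises(ConfigurationError, match="shape"):
            generate_expression(cfg, truth, np.zeros((3, 3)), genes)

    def test_null_coefficients_give_flat_expression(self):
        cfg = small(true_coefficients=[0.0] * 4, noise_sd=0.0,
                    replicate_jitter_sd=0.0)
        res = simulate(cfg)
        t = res.expression.slice("target").values
        np.testing.assert_allclose(t, t[0, 0])

    def test_enriched_genes_have_constructed_fold_change(self, sim_result):
        expr = sim_result.expression
        t = expr.slice("target").values.mean(axis=1)
        r = expr.slice("ref1").values.mean(axis=1)
        idx = {g: i for i, g in enumerate(expr.genes)}
        for g in sim_result.truth.enriched_gene_ids:
            i = idx[g]
            if t[i] > 1.0:  # fold-change meaningful above the FPKM floor
                assert t[i] / max(r[i], 1e-9) > 4.0


class TestEmittedFilesRoundTrip:
    def test_readers_reproduce_generator_objects(self, sim_result, sim_dir):
        genes = read_gene_annotation(sim_dir / "genes.tsv")
        assert [(g.gene_id, g.tss, g.strand) for g in genes] == [
            (g.gene_id, g.tss, g.strand) for g in sim_result.genes
        ]
        target = read_bed(sim_dir / "target.bed", q_threshold=1.1)
        assert [(p.start, p.end) for p in target] == [
            (p.start, p.end) for p in sim_result.target
        ]
        pwms = mo.read_jaspar(sim_dir / "pwms.jaspar")
        assert [p.consensus for p in pwms] == [
            p.consensus for p in sim_result.pwms
        ]
        expr = ExpressionTable.read_tsv(sim_dir / "expression.tsv")
        np.testing.assert_allclose(
            expr.values.values, sim_result.expression.values.values, rtol=1e-5
        )


class TestMatrixLevelGenerator:
    def test_ols_recovers_large_coefficient_signs(self):
        # emitted X, y admit a closed-form refit recovering sign structure
        beta = np.array([1.2, 0.0, -0.9, 0.6, 0.0, 0.8, 1.1, 0.0, 0.7, -0.6, 1.3])
        st = simulate_promoter_hits(n_genes=59, n_tfs=11, seed=3,
                                    scheme="pval", beta=beta)
        A = np.column_stack([np.ones(59), st.X])
        coef = np.linalg.lstsq(A, st.y, rcond=None)[0][1:]
        for j, b in enumerate(beta):
            if abs(b) > 0.5:
                assert np.sign(coef[j]) == np.sign(b)

    def test_noise_calibration_hits_target_r2(self):
        st = simulate_promoter_hits(n_genes=400, seed=6, scheme="pval",
                                    target_r2=0.7)
        signal = st.beta0 + st.X @ st.beta
        r2 = np.var(signal) / (np.var(signal) + st.noise_sd ** 2)
        assert r2 == pytest.approx(0.7, abs=1e-9)
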