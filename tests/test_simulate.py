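import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from occupeak import annotate, metagene, motifs, temporal
from occupeak.formats_io import (
    read_expression_table,
    read_gene_models,
    read_motif_meme,
    read_peaks_bed,
    read_signal_bedgraph,
)
from occupeak.simulate import (
    SimulationConfig,
    SimulationError,
    consensus_pwm,
    simulate_expression,
    simulate_genes,
    simulate_genome,
    simulate_signal_tracks,
    simulate_study,
)


def tiny_config(**overrides):
    kwargs = dict(
        seed=3,
        n_chromosomes=1,
        chrom_length=300_000,
        n_genes=15,
        gene_length_min=5_000,
        gene_length_max=10_000,
        peaks_per_cell=1,
        n_up=3,
        n_down=2,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestGenome:
    def test_determinism(self):
        g1 = simulate_genome(tiny_config(), np.random.default_rng(1))
        g2 = simulate_genome(tiny_config(), np.random.default_rng(1))
        assert all(np.array_equal(g1[c], g2[c]) for c in g1)

    def test_gc_content_within_binomial_ci(self):
        cfg = tiny_config(gc_content=0.5)
        genome = simulate_genome(cfg, np.random.default_rng(0))
        codes = genome["chr1"]
        gc = int(np.sum((codes == 1) | (codes == 2)))
        assert sps.binomtest(gc, codes.size, 0.5).pvalue > 0.001

    def test_zero_chromosomes_error(self):
        with pytest.raises(SimulationError):
            simulate_genome(tiny_config(n_chromosomes=0),
                            np.random.default_rng(0))


class TestGenes:
    def test_non_overlapping(self):
        cfg = tiny_config(n_genes=25, chrom_length=800_000)
        genes = simulate_genes(cfg, {"chr1": cfg.chrom_length},
                               np.random.default_rng(2))
        assert len(genes) == 25
        spans = sorted((g.tx_start, g.tx_end) for g in genes)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 <= s1

    def test_exon_tiling_invariant(self):
        cfg = tiny_config()
        genes = simulate_genes(cfg, {"chr1": cfg.chrom_length},
                               np.random.default_rng(2))
        for g in genes:
            assert g.exons[0][0] == g.tx_start
            assert g.exons[-1][1] == g.tx_end
            assert 2 <= len(g.exons) <= 8

    def test_both_strands_represented(self):
        cfg = tiny_config(n_genes=30, chrom_length=1_000_000)
        genes = simulate_genes(cfg, {"chr1": cfg.chrom_length},
                               np.random.default_rng(0))
        n_plus = sum(1 for g in genes if g.strand == "+")
        assert sps.binomtest(n_plus, len(genes), 0.5).pvalue > 0.001


class TestPeaksets:
    def test_every_cell_populated(self, small_sim):
        truth = small_sim.truth.regions_frame()
        cells = set(zip(truth["pattern"].astype(str).str.zfill(3),
                        truth["category"]))
        assert len(cells) == 42

    def test_constitutive_pattern_in_all_files(self, small_sim):
        truth = small_sim.truth.regions_frame()
        r = truth[truth["pattern"].astype(str).str.zfill(3) == "111"].iloc[0]
        for peaks in small_sim.peak_sets:
            assert any(
                p.interval.start <= r["anchor"] < p.interval.end
                and p.interval.chrom == r["chrom"]
                for p in peaks
            )

    def test_retained_peaks_pass_significance(self, small_sim):
        for peaks in small_sim.peak_sets:
            assert all(p.neglog10_p >= 10.0 for p in peaks)

    def test_category_truth_consistent_with_classifier(self, small_sim):
        index = annotate.GeneRegionIndex(small_sim.genes,
                                         chrom_sizes=small_sim.chrom_sizes)
        for r in small_sim.truth.regions:
            cat, gene = index.classify_point(r.chrom, r.anchor)
            assert cat == r.category
            assert (gene or "") == r.gene_id


class TestMotifsAndConservation:
    def test_zero_jitter_puts_sites_at_summits(self):
        cfg = tiny_config(motif_jitter_sd=(0.0, 0.0, 0.0))
        res = simulate_study(cfg)
        assert all(r.motif_offset == 0 for r in res.truth.regions)

    def test_planted_word_present_in_sequence(self, small_sim):
        consensus = small_sim.config.motif_consensus
        rc = motifs.reverse_complement(consensus)
        for r in small_sim.truth.regions[:50]:
            seq = small_sim.sequences[r.chrom]
            word = seq[r.motif_start : r.motif_start + len(consensus)]
            assert word == (consensus if r.motif_strand == "+" else rc)

    def test_conservation_offset_at_down_sites(self, small_sim):
        cons = small_sim.conservation
        w = len(small_sim.config.motif_consensus)
        down_scores, other_scores = [], []
        for r in small_sim.truth.regions:
            score = cons.mean(r.chrom, r.motif_start, r.motif_start + w)
            cls = small_sim.gene_classes.get(r.gene_id)
            (down_scores if cls == "down" else other_scores).append(score)
        assert np.mean(down_scores) - np.mean(other_scores) == pytest.approx(
            small_sim.config.conservation_offset, abs=0.15
        )


class TestSignalTracks:
    def test_no_peaks_gives_flat_ratios(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        genes = simulate_genes(cfg, {"chr1": cfg.chrom_length}, rng)
        ip_tracks, input_track = simulate_signal_tracks(
            cfg, [[], [], []], genes, {}, {"chr1": cfg.chrom_length}, rng
        )
        schema = metagene.build_window_schema(genes[5])
        profile = metagene.window_signal_ratio(schema, ip_tracks[1], input_track)
        assert np.allclose(profile.values, 1.0, atol=0.05)

    def test_bump_amplitude_drives_window_ratio(self):
        from occupeak.formats_io import GenomicInterval, Peak

        cfg = tiny_config(bump_scale=0.05, input_noise_sd=0.0)
        rng = np.random.default_rng(0)
        # amplitude = 200 * 0.05 = 10x the unit baseline
        peak = Peak(GenomicInterval("chr1", 149_900, 150_100), "p", 15.0,
                    100, 200.0)
        ip_tracks, input_track = simulate_signal_tracks(
            cfg, [[peak], [], []], [], {}, {"chr1": cfg.chrom_length}, rng
        )
        window_ratio = (
            ip_tracks[0].mean("chr1", 149_500, 150_500) + 0.5
        ) / (input_track.mean("chr1", 149_500, 150_500) + 0.5)
        assert window_ratio > 2.0

    def test_deterministic_under_seed(self):
        runs = []
        for _ in range(2):
            cfg = tiny_config()
            res = simulate_study(cfg)
            runs.append(list(res.input_track.records())[:100])
        assert runs[0] == runs[1]


class TestExpression:
    def test_null_effect_false_positive_rate(self):
        from occupeak import integrate

        cfg = tiny_config(expression_effect_log2=0.0, n_genes=200)
        rng = np.random.default_rng(0)
        gene_ids = [f"g{i}" for i in range(200)]
        classes = {g: "nonresponsive" for g in gene_ids}
        expr = simulate_expression(cfg, gene_ids, classes, rng)
        de = integrate.moderated_t_de(expr, "knockdown", "control")
        # without effects, nothing should survive FDR control (approximately)
        classified = integrate.classify_genes(de)
        counts = integrate.class_counts(classified)
        assert counts["up"] + counts["down"] <= 0.05 * 200

    def test_recovery_of_planted_genes(self, small_sim):
        from occupeak import integrate

        de = integrate.moderated_t_de(small_sim.expression, "knockdown",
                                      "control")
        classified = integrate.classify_genes(de)
        truth = {g.gene_id: g.gene_class for g in small_sim.truth.genes}
        got = dict(zip(classified["gene_id"], classified["gene_class"]))
        planted = [g for g, c in truth.items() if c != "nonresponsive"]
        recovered = sum(1 for g in planted if got[g] == truth[g])
        assert recovered >= 0.9 * len(planted)

    def test_deterministic_under_seed(self):
        cfg = tiny_config()
        ids = ["a", "b", "c"]
        classes = {"a": "up", "b": "down", "c": "nonresponsive"}
        e1 = simulate_expression(cfg, ids, classes, np.random.default_rng(4))
        e2 = simulate_expression(cfg, ids, classes, np.random.default_rng(4))
        assert np.array_equal(e1.values, e2.values)


class TestEmittedFiles:
    def test_roundtrip_through_readers(self, small_sim):
        paths = small_sim.paths
        genes = read_gene_models(paths["genes"])
        assert genes == small_sim.genes
        for t, label in enumerate(("d0", "d9", "d28")):
            peaks = read_peaks_bed(paths[f"peaks_{label}"])
            assert peaks == small_sim.peak_sets[t]
        track = read_signal_bedgraph(paths["input"])
        for (c1, s1, e1, v1), (c2, s2, e2, v2) in zip(
            list(track.records())[:200],
            list(small_sim.input_track.records())[:200],
        ):
            assert (c1, s1, e1) == (c2, s2, e2)
            assert v1 == pytest.approx(v2, rel=1e-5)
        pwm = read_motif_meme(paths["motif"])
        assert pwm.consensus == small_sim.pwm.consensus
        conds = {
            "control": [f"ctrl_{i+1}" for i in range(3)],
            "knockdown": [f"kd_{i+1}" for i in range(3)],
        }
        expr = read_expression_table(paths["expression"], conds)
        assert np.array_equal(expr.values, small_sim.expression.values)

    def test_byte_identical_reruns(self, small_config, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate_study(dataclasses.replace(small_config), out1)
        simulate_study(dataclasses.replace(small_config), out2)
        for name in ("genome.fa", "genes.bed12", "peaks_d9.bed",
                     "expression.tsv", "truth_regions.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


class TestPWM:
    def test_consensus_pwm_roundtrip(self):
        pwm = consensus_pwm("TGTGGTTT")
        assert pwm.consensus == "TGTGGTTT"
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
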