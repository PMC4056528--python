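import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from occupeak import integrate
from occupeak.formats_io import ExpressionMatrix, GenomicInterval, Peak, SignalTrack
from occupeak.motifs import MotifHit
from occupeak.stats import bh_fdr


def make_expr(values, reps=3):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    samples = [f"c{i}" for i in range(reps)] + [f"t{i}" for i in range(reps)]
    conditions = {s: ("ctrl" if s.startswith("c") else "treat") for s in samples}
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        samples=samples,
        conditions=conditions,
        values=values,
    )


class TestModeratedT:
    def test_single_gene_equals_ordinary_t(self):
        vals = np.array([[1.0, 1.2, 0.9, 2.0, 2.3, 1.9]])
        de = integrate.moderated_t_de(make_expr(vals), "treat", "ctrl")
        t_ref, p_ref = sps.ttest_ind(vals[0, 3:], vals[0, :3], equal_var=True)
        assert de.loc[0, "t"] == pytest.approx(t_ref)
        assert de.loc[0, "p"] == pytest.approx(p_ref)
        assert de.loc[0, "df_prior"] == 0.0

    def test_constant_variances_infinite_prior(self):
        # every gene has identical pooled variance -> d0 estimated infinite
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            base = rng.normal()
            shift = rng.normal()
            rows.append([base, base + 1.0, base + 2.0,
                         shift, shift + 1.0, shift + 2.0])
        de = integrate.moderated_t_de(make_expr(np.array(rows)), "treat", "ctrl")
        assert math.isinf(de.loc[0, "df_prior"])
        # t proportional to the mean difference with a common scale
        diffs = de["log2fc"].to_numpy()
        ts = de["t"].to_numpy()
        ratio = ts[np.abs(diffs) > 1e-9] / diffs[np.abs(diffs) > 1e-9]
        assert np.allclose(ratio, ratio[0])

    def test_zero_variance_everywhere_falls_back(self):
        vals = np.tile([1.0, 1.0, 1.0, 2.0, 2.0, 2.0], (5, 1))
        de = integrate.moderated_t_de(make_expr(vals), "treat", "ctrl")
        assert np.all(np.isfinite(de["p"]))

    def test_needs_two_replicates(self):
        expr = ExpressionMatrix(
            gene_ids=["g0"],
            samples=["c0", "c1", "t0", "t1"],
            conditions={"c0": "ctrl", "c1": "ctrl", "t0": "treat", "t1": "treat"},
            values=np.array([[1.0, 2.0, 3.0, 4.0]]),
        )
        de = integrate.moderated_t_de(expr, "treat", "ctrl")
        assert len(de) == 1

    def test_moderation_beats_ordinary_t_at_matched_fdr(self):
        # known DE genes; compare true positives of the largest rejection set
        # whose empirical FDR stays below 0.05
        rng = np.random.default_rng(5)
        n_genes, n_de = 1000, 100
        sds = 0.2 * np.exp(rng.normal(0, 0.4, n_genes))
        truth = np.zeros(n_genes, dtype=bool)
        truth[:n_de] = True
        effect = np.where(truth, 1.0, 0.0)
        base = rng.normal(8, 1, n_genes)
        ctrl = base[:, None] + rng.normal(0, sds[:, None], (n_genes, 3))
        treat = (base + effect)[:, None] + rng.normal(
            0, sds[:, None], (n_genes, 3)
        )
        expr = make_expr(np.hstack([ctrl, treat]))
        de = integrate.moderated_t_de(expr, "treat", "ctrl")
        t_ord, p_ord = sps.ttest_ind(treat, ctrl, axis=1, equal_var=True)

        def tp_at_fdr(pvals, alpha=0.05):
            order = np.argsort(pvals)
            best = 0
            fp = tp = 0
            for k, i in enumerate(order, start=1):
                tp += truth[i]
                fp += not truth[i]
                if fp / k <= alpha:
                    best = tp
            return best

        assert tp_at_fdr(de["p"].to_numpy()) >= tp_at_fdr(p_ord)


class TestClassifyGenes:
    def _frame(self, log2fc, p):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(p))],
             "log2fc": log2fc, "t": 0.0, "p": p}
        )

    def test_nonresponsive(self):
        df = integrate.classify_genes(self._frame([0.0], [0.9]))
        assert df.loc[0, "gene_class"] == integrate.NONRESPONSIVE

    def test_twofold_up(self):
        df = integrate.classify_genes(self._frame([1.0], [0.01]))
        assert df.loc[0, "gene_class"] == integrate.UP

    def test_strict_log2_mode(self):
        df = integrate.classify_genes(
            self._frame([1.0], [0.01]), strict_log2=True
        )
        assert df.loc[0, "gene_class"] == integrate.NONRESPONSIVE

    def test_class_counts_conserve(self):
        rng = np.random.default_rng(0)
        df = integrate.classify_genes(
            self._frame(rng.normal(0, 1, 200), rng.uniform(0, 1, 200))
        )
        counts = integrate.class_counts(df)
        assert sum(counts.values()) == 200

    def test_planted_counts_recovered(self, small_sim):
        de = integrate.moderated_t_de(
            small_sim.expression, "knockdown", "control"
        )
        classified = integrate.classify_genes(de)
        truth = {g.gene_id: g.gene_class for g in small_sim.truth.genes}
        got = dict(zip(classified["gene_id"], classified["gene_class"]))
        planted_up = sum(1 for g, c in truth.items() if c == integrate.UP)
        planted_down = sum(1 for g, c in truth.items() if c == integrate.DOWN)
        found_up = sum(
            1 for g, c in got.items()
            if c == integrate.UP and truth[g] == integrate.UP
        )
        found_down = sum(
            1 for g, c in got.items()
            if c == integrate.DOWN and truth[g] == integrate.DOWN
        )
        assert found_up >= 0.9 * planted_up
        assert found_down >= 0.9 * planted_down


class TestPeaksPerGene:
    def _mapping(self, counts):
        mapping = {}
        for gid, n in counts.items():
            mapping[gid] = [
                Peak(GenomicInterval("chr1", 100 * (i + 1), 100 * (i + 1) + 50),
                     f"{gid}_{i}")
                for i in range(n)
            ]
        return mapping

    def test_exact_example(self):
        classes = {"d1": "down", "d2": "down", "d3": "down",
                   "n1": "nonresponsive", "n2": "nonresponsive",
                   "n3": "nonresponsive"}
        mapping = self._mapping({"d1": 3, "d2": 5, "d3": 4,
                                 "n1": 1, "n2": 1, "n3": 2})
        df = integrate.peaks_per_gene_test(mapping, classes).set_index("gene_class")
        assert df.loc["down", "mean_peaks_per_gene"] == pytest.approx(4.0)
        assert df.loc["down", "p_vs_nonresponsive"] == pytest.approx(0.1)

    def test_identical_distributions(self):
        classes = {"a": "down", "b": "nonresponsive"}
        mapping = self._mapping({"a": 2, "b": 2})
        df = integrate.peaks_per_gene_test(mapping, classes).set_index("gene_class")
        assert df.loc["down", "p_vs_nonresponsive"] == 1.0

    def test_planted_excess_significant(self):
        rng = np.random.default_rng(0)
        classes = {}
        counts = {}
        for i in range(30):
            classes[f"d{i}"] = "down"
            counts[f"d{i}"] = int(rng.poisson(6))
        for i in range(30):
            classes[f"n{i}"] = "nonresponsive"
            counts[f"n{i}"] = int(rng.poisson(2))
        df = integrate.peaks_per_gene_test(
            self._mapping(counts), classes
        ).set_index("gene_class")
        assert df.loc["down", "p_vs_nonresponsive"] < 0.05


class TestFoldchangeByLocation:
    def test_log2_ratio(self):
        peak = Peak(GenomicInterval("chr1", 0, 100), "p0")
        df = integrate.foldchange_by_location(
            {"g": [peak]},
            {"g": "down"},
            {"p0": "promoter"},
            {"p0": math.log2(2.0)},
            {"p0": math.log2(8.0)},
        )
        assert df.loc[0, "mean_log2fc"] == pytest.approx(2.0)

    def test_nonresponsive_vs_itself(self):
        peak = Peak(GenomicInterval("chr1", 0, 100), "p0")
        df = integrate.foldchange_by_location(
            {"g": [peak]}, {"g": "nonresponsive"}, {"p0": "intron"},
            {"p0": 1.0}, {"p0": 2.0},
        )
        assert df.loc[0, "p_vs_nonresponsive"] == 1.0

    def test_promoter_specific_gain_detected(self):
        rng = np.random.default_rng(1)
        gene_peaks = {}
        classes = {}
        categories = {}
        i0, i1 = {}, {}
        k = 0
        for cls, gain in (("down", 2.0), ("nonresponsive", 0.0)):
            for g in range(25):
                gid = f"{cls}_{g}"
                classes[gid] = cls
                peaks = []
                for cat in ("promoter", "intergenic"):
                    name = f"pk{k}"; k += 1
                    peaks.append(Peak(GenomicInterval("chr1", k * 100,
                                                      k * 100 + 50), name))
                    categories[name] = cat
                    i0[name] = rng.normal(5, 0.3)
                    delta = gain if cat == "promoter" else 0.0
                    i1[name] = i0[name] + delta + rng.normal(0, 0.3)
                gene_peaks[gid] = peaks
        df = integrate.foldchange_by_location(
            gene_peaks, classes, categories, i0, i1
        ).set_index(["category", "gene_class"])
        assert df.loc[("promoter", "down"), "p_vs_nonresponsive"] < 0.05
        assert df.loc[("intergenic", "down"), "p_vs_nonresponsive"] > 0.05


class TestGeneConservation:
    def test_site_weighted_mean(self):
        track = SignalTrack.from_records([("chr1", 0, 4, 2.0), ("chr1", 4, 6, 0.0)])
        peak = Peak(GenomicInterval("chr1", 0, 50), "p0")
        hit = MotifHit(GenomicInterval("chr1", 0, 6), "+", 10.0, 1e-5)
        summaries, n_excl = integrate.gene_conservation(
            {"g": [peak]}, {"p0": hit}, track
        )
        assert summaries["g"].mean_phylop == pytest.approx(8.0 / 6.0)
        assert n_excl == 0

    def test_gene_score_averages_sites(self):
        track = SignalTrack.from_records(
            [("chr1", 0, 10, 1.0), ("chr1", 100, 110, 3.0)]
        )
        peaks = [Peak(GenomicInterval("chr1", 0, 50), "p0"),
                 Peak(GenomicInterval("chr1", 90, 140), "p1")]
        hits = {
            "p0": MotifHit(GenomicInterval("chr1", 2, 8), "+", 9.0, 1e-5),
            "p1": MotifHit(GenomicInterval("chr1", 102, 108), "+", 9.0, 1e-5),
        }
        summaries, _ = integrate.gene_conservation({"g": peaks}, hits, track)
        assert summaries["g"].mean_phylop == pytest.approx(2.0)
        assert summaries["g"].n_sites == 2

    def test_gene_without_sites_excluded(self):
        track = SignalTrack.from_records([("chr1", 0, 10, 1.0)])
        peak = Peak(GenomicInterval("chr1", 0, 50), "p0")
        summaries, n_excl = integrate.gene_conservation(
            {"g": [peak]}, {"p0": None}, track
        )
        assert summaries == {} and n_excl == 1


class TestLengthMatching:
    def test_nearest_length(self):
        matches, diag = integrate.length_matched_controls(
            {"t1": 1000, "t2": 5000}, {"c1": 900, "c2": 1100, "c3": 5200},
        )
        assert matches["t2"] == "c3"
        assert matches["t1"] in ("c1", "c2")
        assert diag["max_abs_delta"] == 200.0

    def test_self_match(self):
        lengths = {f"g{i}": 1000 + 7 * i for i in range(10)}
        matches, diag = integrate.length_matched_controls(lengths, dict(lengths))
        assert diag["max_abs_delta"] == 0.0
        assert matches == {g: g for g in lengths}

    def test_pool_smaller_than_targets(self):
        with pytest.raises(integrate.MatchingError):
            integrate.length_matched_controls({"a": 1, "b": 2}, {"c": 1})

    def test_matched_distribution_not_rejected_by_ks(self):
        rng = np.random.default_rng(0)
        targets = {f"t{i}": int(l) for i, l in
                   enumerate(rng.lognormal(9, 0.5, 200))}
        pool = {f"p{i}": int(l) for i, l in
                enumerate(rng.lognormal(9, 0.5, 1000))}
        matches, _ = integrate.length_matched_controls(targets, pool, seed=1)
        res = sps.ks_2samp(
            list(targets.values()), [pool[m] for m in matches.values()]
        )
        assert res.pvalue > 0.05


class TestConservationKS:
    def _summaries(self, values):
        return [
            integrate.ConservationSummary(f"g{i}", v, 1)
            for i, v in enumerate(values)
        ]

    def test_identical(self):
        res = integrate.conservation_ks(
            self._summaries([1, 2, 3]), self._summaries([1, 2, 3])
        )
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint(self):
        res = integrate.conservation_ks(
            self._summaries([0.1, 0.2, 0.3, 0.4]),
            self._summaries([1.1, 1.2, 1.3, 1.4]),
        )
        assert res.statistic == 1.0

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            integrate.conservation_ks(
                self._summaries([1, 2]), self._summaries([1, 2, 3])
            )


class TestBHFDRControl:
    def test_null_fdr_controlled(self):
        # rejecting at q < alpha controls empirical false-rejection rate
        rng = np.random.default_rng(0)
        n_reject = 0
        n_tests = 0
        for _ in range(200):
            p = rng.uniform(size=50)
            n_reject += int(np.sum(bh_fdr(p) < 0.05))
            n_tests += 1
        # under the global null, expected rejections per repetition <= alpha
        assert n_reject / n_tests <= 0.05 * 50
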