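import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aneudose as ad
from aneudose.threshold_caller import ThresholdSpec, difference_matrix


def _make_rt(rows, comparisons):
    data = pd.DataFrame(
        rows, columns=["gene_id", "comparison_id", "replicate", "molecule", "log2_ratio"]
    )
    comps = pd.DataFrame(
        [{"comparison_id": c, "test_strain": s, "ref_strain": "eu"} for c, s in comparisons]
    ).set_index("comparison_id")
    return ad.RatioTable(data, comps)


def _make_ann(genes, chromosome="chr01", amplified_in=("A",)):
    return ad.GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "length_bp": 1000,
                "amplified_in": [frozenset(amplified_in)] * len(genes),
                "categories": [frozenset()] * len(genes),
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )


class TestChromosomeSd:
    def test_hand_computed(self):
        rt = _make_rt(
            [("g1", "c", 1, "DNA", 1.0), ("g2", "c", 1, "DNA", 1.2),
             ("g3", "c", 1, "DNA", 0.8)],
            [("c", "A")],
        )
        ann = _make_ann(["g1", "g2", "g3"])
        assert ad.chromosome_sd(rt, ann, "c") == pytest.approx(0.2)

    def test_constant_ratios_rejected(self):
        rt = _make_rt(
            [("g1", "c", 1, "DNA", 1.0), ("g2", "c", 1, "DNA", 1.0)],
            [("c", "A")],
        )
        with pytest.raises(ValueError, match="degenerate"):
            ad.chromosome_sd(rt, _make_ann(["g1", "g2"]), "c")

    def test_too_few_genes_rejected(self):
        rt = _make_rt([("g1", "c", 1, "DNA", 1.0)], [("c", "A")])
        with pytest.raises(ValueError, match=">=2"):
            ad.chromosome_sd(rt, _make_ann(["g1"]), "c")

    def test_recovers_generative_sd(self, pair_sim):
        cm, ann, gt, rt = pair_sim
        cfg = ad.SimConfig()
        sd = ad.chromosome_sd(rt, ann, "aneu1_vs_eu1")
        target = np.sqrt(cfg.dosage_sd ** 2 + 2 * cfg.dna_measurement_sd ** 2)
        assert sd == pytest.approx(target, rel=0.2)


class TestGeneThresholds:
    def _rt(self):
        rows = [("g1", "c", 1, "DNA", 1.0), ("g2", "c", 1, "DNA", 1.2),
                ("g3", "c", 1, "DNA", 0.8)]
        return _make_rt(rows, [("c", "A")])

    def test_one_sd_threshold(self):
        # DNA ratio 1.0 minus one chromosome SD of 0.197
        spec = ThresholdSpec(k_sd=1.0, sd_chr={"c": 0.197})
        thr = ad.gene_thresholds(self._rt(), _make_ann(["g1", "g2", "g3"]), "c", spec)
        assert thr["g1"] == pytest.approx(0.803)

    def test_three_sd_threshold(self):
        spec = ThresholdSpec(k_sd=3.0, sd_chr={"c": 0.2})
        thr = ad.gene_thresholds(self._rt(), _make_ann(["g1", "g2", "g3"]), "c", spec)
        assert thr["g1"] == pytest.approx(0.4)

    def test_k_zero_is_identity(self):
        spec = ThresholdSpec(k_sd=0.0, sd_chr={"c": 0.2})
        thr = ad.gene_thresholds(self._rt(), _make_ann(["g1", "g2", "g3"]), "c", spec)
        assert thr["g2"] == pytest.approx(1.2)


class TestCallRule:
    def _fixture(self, rep_values):
        # two comparisons, gene-specific threshold 0.803 in both
        rows = []
        for comp in ("c1", "c2"):
            rows += [("g1", comp, 1, "DNA", 1.0), ("g2", comp, 1, "DNA", 1.2)]
            for rep, v in enumerate(rep_values, start=1):
                rows.append(("g1", comp, rep, "RNA", v))
                rows.append(("g2", comp, rep, "RNA", 1.2))
        rt = _make_rt(rows, [("c1", "A"), ("c2", "A")])
        ann = _make_ann(["g1", "g2"])
        spec = ThresholdSpec(k_sd=1.0, sd_chr={"c1": 0.197, "c2": 0.197})
        return rt, ann, spec

    def test_all_replicates_below_is_called(self):
        rt, ann, spec = self._fixture([0.70, 0.75])
        cs = ad.call_lower_expressed(rt, ann, spec, ["c1", "c2"])
        assert bool(cs.calls.loc["g1", "called"])
        assert cs.calls.loc["g1", "n_replicates"] == 4

    def test_one_replicate_above_is_not_called(self):
        rt, ann, spec = self._fixture([0.70, 0.85])
        cs = ad.call_lower_expressed(rt, ann, spec, ["c1", "c2"])
        assert not bool(cs.calls.loc["g1", "called"])

    def test_tie_is_not_called(self):
        rt, ann, spec = self._fixture([0.803, 0.70])
        cs = ad.call_lower_expressed(rt, ann, spec, ["c1", "c2"])
        assert not bool(cs.calls.loc["g1", "called"])

    def test_effect_size_definition(self):
        rt, ann, spec = self._fixture([0.70, 0.80])
        cs = ad.call_lower_expressed(rt, ann, spec, ["c1", "c2"])
        assert cs.calls.loc["g1", "effect_size"] == pytest.approx(0.75 - 1.0)

    def test_missing_gene_not_assessed(self):
        rt, ann, spec = self._fixture([0.70, 0.75])
        # drop g1's mRNA in c2 entirely
        data = rt.data[~((rt.data["gene_id"] == "g1")
                         & (rt.data["comparison_id"] == "c2")
                         & (rt.data["molecule"] == "RNA"))]
        rt2 = ad.RatioTable(data.reset_index(drop=True), rt.comparisons)
        cs = ad.call_lower_expressed(rt2, ann, spec, ["c1", "c2"])
        assert "g1" in cs.not_assessed
        assert "g1" not in cs.calls.index


class TestMonotonicity:
    def test_k3_subset_of_k1(self, pair_sim):
        cm, ann, gt, rt = pair_sim
        c1 = ad.call_lower_expressed(rt, ann, ThresholdSpec(k_sd=1.0))
        c3 = ad.call_lower_expressed(rt, ann, ThresholdSpec(k_sd=3.0))
        assert set(c3.called_genes) <= set(c1.called_genes)

    def test_calls_non_increasing_in_k(self, pair_sim):
        cm, ann, gt, rt = pair_sim
        counts = [
            len(ad.call_lower_expressed(rt, ann, ThresholdSpec(k_sd=k)).called_genes)
            for k in (0.5, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMatchedUnamplified:
    def test_threshold_uses_amplified_sd(self):
        rows = [("a1", "c", 1, "DNA", 1.0), ("a2", "c", 1, "DNA", 1.2),
                ("a3", "c", 1, "DNA", 0.8), ("u1", "c", 1, "DNA", 0.0),
                ("u1", "c", 1, "RNA", -0.7), ("u1", "c", 2, "RNA", -0.65)]
        rt = _make_rt(rows, [("c", "A")])
        ann = ad.GeneAnnotation(
            pd.DataFrame(
                {
                    "chromosome": ["chr01"] * 3 + ["chr02"],
                    "length_bp": 1000,
                    "amplified_in": [frozenset({"A"})] * 3 + [frozenset()],
                    "categories": [frozenset()] * 4,
                },
                index=pd.Index(["a1", "a2", "a3", "u1"], name="gene_id"),
            )
        )
        spec = ThresholdSpec(k_sd=3.0)   # amplified-chromosome SD = 0.2
        cs = ad.matched_unamplified_calls(rt, ann, spec, ["c"])
        thr = cs.thresholds.set_index("gene_id")["threshold"]
        assert thr["u1"] == pytest.approx(0.0 - 3 * 0.2)

    def test_call_flags(self):
        rows = [("a1", "c", 1, "DNA", 1.0), ("a2", "c", 1, "DNA", 1.2),
                ("a3", "c", 1, "DNA", 0.8), ("u1", "c", 1, "DNA", 0.0),
                ("u1", "c", 1, "RNA", -0.7), ("u1", "c", 2, "RNA", -0.65)]
        rt = _make_rt(rows, [("c", "A")])
        ann = ad.GeneAnnotation(
            pd.DataFrame(
                {
                    "chromosome": ["chr01"] * 3 + ["chr02"],
                    "length_bp": 1000,
                    "amplified_in": [frozenset({"A"})] * 3 + [frozenset()],
                    "categories": [frozenset()] * 4,
                },
                index=pd.Index(["a1", "a2", "a3", "u1"], name="gene_id"),
            )
        )
        cs = ad.matched_unamplified_calls(rt, ann, ThresholdSpec(k_sd=3.0), ["c"])
        assert bool(cs.calls.loc["u1", "called"])   # both reps below -0.6

    def test_null_call_rate_matches_normal_tail_oracle(self, pair_sim):
        # unamplified genes have DNA ratios ~ N(0, s_d) and replicate
        # mRNA ratios ~ N(0, s_r): P(call) = E[Phi((d - k*sd)/s_r)^R]
        cm, ann, gt, rt = pair_sim
        comps = ["aneu1_vs_eu1"]
        spec = ThresholdSpec(k_sd=1.0)
        cs = ad.matched_unamplified_calls(rt, ann, spec, comps)
        # restrict to genes without trans effects (default sim has none)
        rate = len(cs.called_genes) / cs.n_assessed
        sd_chr = ad.chromosome_sd(rt, ann, comps[0])
        unamp = ann.unamplified_genes("aneu1")
        dna = rt.dna(comps[0]).reindex(unamp).dropna()
        m = rt.mrna(comps[0]).reindex(unamp).dropna()
        s_d, s_r = float(dna.std()), float(np.sqrt(m.var(axis=1, ddof=1).mean()))
        z, w = np.polynomial.hermite_e.hermegauss(61)
        oracle = float(
            np.sum(
                w / np.sqrt(2 * np.pi)
                * stats.norm.cdf((z * s_d - sd_chr) / s_r) ** m.shape[1]
            )
        )
        assert rate == pytest.approx(oracle, abs=0.02)

    def test_trans_repressed_genes_are_called(self):
        cfg = ad.default_pair_config(
            n_genes=1000, seed=21,
            trans_modules=({"category": "mod", "effect_log2": -1.0, "n_genes": 40},),
        )
        cm, ann, gt = ad.simulate_pair(cfg)
        abund = ad.rpkm_normalize(cm, ann, exclude_chromosomes=["chr01"])
        rt = ad.log2_ratios(abund, cm.samples, ad.pair_comparisons(cm))
        cs = ad.matched_unamplified_calls(rt, ann, ThresholdSpec(k_sd=1.0))
        members = gt.genes.index[(gt.genes["module"] == "mod") & ~gt.genes["amplified"]]
        called = set(cs.called_genes)
        assert np.mean([g in called for g in members]) > 0.8


class TestPermutationFdr:
    def test_analytic_oracle_four_columns(self):
        # symmetric null d-values, 4 independent columns -> null calls G/16
        rng = np.random.default_rng(0)
        G = 1600
        d = rng.normal(size=(G, 4))
        res = ad.permutation_fdr(d, n_iter=4000, seed=1)
        neg = (d < 0).mean(axis=0)
        expected = G * float(np.prod(neg))
        se = res.null_counts.std() / np.sqrt(len(res.null_counts))
        assert abs(res.mean_null_count - expected) < 4 * se + 0.5

    def test_saturation(self):
        d = -np.ones((50, 3))
        res = ad.permutation_fdr(d, n_iter=200, seed=0)
        assert res.observed_count == 50
        assert res.fdr == pytest.approx(1.0)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(200, 2))
        a = ad.permutation_fdr(d, n_iter=500, seed=9)
        b = ad.permutation_fdr(d, n_iter=500, seed=9)
        assert a.fdr == b.fdr
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_no_observed_calls_flagged(self):
        d = np.ones((50, 2))
        res = ad.permutation_fdr(d, n_iter=100, seed=0)
        assert res.undefined and np.isnan(res.fdr)


class TestEstimator:
    def test_fit_attributes_and_params(self, pair_sim):
        cm, ann, gt, rt = pair_sim
        est = ad.ThresholdCaller(k_sd=1.0, n_permutations=200, random_state=0)
        assert est.get_params()["k_sd"] == 1.0
        est.set_params(k_sd=3.0)
        est.fit(rt, ann)
        assert hasattr(est, "calls_") and hasattr(est, "fdr_estimate_")
        assert est.predict().dtype == bool
        from sklearn.base import clone
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
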