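import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aneudose as ad
from aneudose.io_normalize import CategoryMap
from aneudose.response_filter import (
    call_de_unamplified,
    enrich_categories,
    filter_amplified_calls,
    partition_by_effect,
    select_lower_expressed,
    strain_enrichment,
)


@pytest.fixture(scope="module")
def trans_sim():
    """Pair design with a strong repressed trans module that also touches
    amplified genes (the indirect-response scenario the filter targets)."""
    cfg = ad.default_pair_config(
        n_genes=1200,
        n_rna_reps=3,
        seed=33,
        trans_modules=(
            {"category": "stress_mod", "effect_log2": -1.0, "n_genes": 60,
             "n_amplified": 10},
        ),
    )
    cm, ann, gt = ad.simulate_pair(cfg)
    return cm, ann, gt


class TestDE:
    def test_identical_counts_not_selected(self, tiny_dataset):
        cm, ann = tiny_dataset
        counts = cm.counts.copy()
        samples = cm.samples.copy()
        # build 2 replicates per strain with identical counts
        for rep in (2,):
            for s in ["eu_RNA_r1", "aneu_RNA_r1"]:
                name = s.replace("r1", f"r{rep}")
                counts[name] = counts[s]
                samples.loc[name] = samples.loc[s]
                samples.loc[name, "replicate"] = rep
        counts["aneu_RNA_r1"] = counts["eu_RNA_r1"]
        counts["aneu_RNA_r2"] = counts["eu_RNA_r2"]
        cm2 = ad.CountMatrix(counts, samples)
        de = call_de_unamplified(cm2, ann, "aneu", "eu")
        assert (de["log2fc"].abs() < 1e-9).all()
        assert len(select_lower_expressed(de)) == 0

    def test_too_few_replicates_directs_to_import(self, tiny_dataset):
        cm, ann = tiny_dataset
        with pytest.raises(ValueError, match="import"):
            call_de_unamplified(cm, ann, "aneu", "eu")

    def test_import_table_passthrough(self, tiny_dataset):
        cm, ann = tiny_dataset
        table = pd.DataFrame(
            {"gene_id": ["g2", "g3"], "log2fc": [-1.0, 0.2],
             "pvalue": [1e-5, 0.4], "fdr": [1e-4, 0.5]}
        )
        de = call_de_unamplified(cm, ann, "aneu", "eu", method="import", de_table=table)
        assert list(select_lower_expressed(de)) == ["g2"]

    def test_trans_module_power(self, trans_sim):
        # module genes shifted by -1 log2 with sd 0.2 and 3 reps are
        # selected at FDR < 0.01 with power >= 0.9
        cm, ann, gt = trans_sim
        de = call_de_unamplified(cm, ann, "aneu", "eu")
        lower = set(select_lower_expressed(de))
        members = gt.genes.index[
            (gt.genes["module"] == "stress_mod") & ~gt.genes["amplified"]
        ]
        power = np.mean([g in lower for g in members])
        assert power >= 0.9

    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2, max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_bruteforce_oracle(self, p):
        # independent BH implementation: q_(i) = min_{j>=i} p_(j)*m/j
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
            ]
            brute[idx] = min(1.0, min(candidates))
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh, brute, atol=1e-12)


class TestEnrichment:
    def test_exact_combinatorial_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        cmap = CategoryMap({"cat": frozenset(universe[:10])})
        query = universe[:5]
        res = enrich_categories(query, cmap, universe)
        expected = math.comb(10, 5) / math.comb(100, 5)
        assert res.loc["cat", "pvalue"] == pytest.approx(expected, rel=1e-9)
        assert res.loc["cat", "overlap"] == 5

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        cmap = CategoryMap({"cat": frozenset(universe[:10])})
        res = enrich_categories(universe[40:45], cmap, universe)
        assert res.loc["cat", "pvalue"] == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        universe = [f"g{i}" for i in range(60)]
        cmap = CategoryMap({"cat": frozenset(universe[:12])})
        p1 = enrich_categories(universe[:6], cmap, universe).loc["cat", "pvalue"]
        relabel = {g: f"x{g}" for g in universe}
        cmap2 = CategoryMap({"cat": frozenset(relabel[g] for g in universe[:12])})
        p2 = enrich_categories(
            [relabel[g] for g in universe[:6]], cmap2, list(relabel.values())
        ).loc["cat", "pvalue"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_query_empty_result(self):
        cmap = CategoryMap({"cat": frozenset({"g1"})})
        res = enrich_categories([], cmap, ["g1", "g2"])
        assert res.empty

    def test_localization_excluded(self):
        universe = [f"g{i}" for i in range(20)]
        cmap = CategoryMap(
            {"cat": frozenset(universe[:5]), "loc": frozenset(universe[:5])},
            localization=frozenset({"loc"}),
        )
        res = enrich_categories(universe[:5], cmap, universe)
        assert "loc" not in res.index
        res2 = enrich_categories(universe[:5], cmap, universe,
                                 exclude_localization=False)
        assert "loc" in res2.index

    def test_query_outside_universe_rejected(self):
        cmap = CategoryMap({"cat": frozenset({"g1"})})
        with pytest.raises(ValueError, match="subset"):
            enrich_categories(["gX"], cmap, ["g1", "g2"])


class TestFilter:
    def _calls(self, genes, strain="aneu"):
        return pd.DataFrame(
            {"effect_size": np.linspace(-1, -0.1, len(genes)), "strain": strain},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_no_enrichment_is_identity(self):
        calls = self._calls(["g1", "g2"])
        cmap = CategoryMap({"cat": frozenset({"g1"})})
        revised, removed = filter_amplified_calls(calls, {}, cmap)
        pd.testing.assert_frame_equal(revised, calls)
        assert removed.empty

    def test_enriched_category_member_removed(self):
        calls = self._calls(["g1", "g2"])
        cmap = CategoryMap({"cat": frozenset({"g1"})})
        enr = {
            "aneu": pd.DataFrame(
                {"pvalue": [1e-6]}, index=pd.Index(["cat"], name="category")
            )
        }
        revised, removed = filter_amplified_calls(calls, enr, cmap)
        assert list(revised.index) == ["g2"]
        assert list(removed.index) == ["g1"]
        assert removed.loc["g1", "enriched_category"] == "cat"

    def test_other_strain_enrichment_ignored(self):
        calls = self._calls(["g1"], strain="aneuB")
        cmap = CategoryMap({"cat": frozenset({"g1"})})
        enr = {"aneuA": pd.DataFrame({"pvalue": [1e-9]},
                                     index=pd.Index(["cat"], name="category"))}
        revised, _ = filter_amplified_calls(calls, enr, cmap)
        assert list(revised.index) == ["g1"]

    def test_idempotent(self, trans_sim):
        cm, ann, gt = trans_sim
        enr = {"aneu": strain_enrichment(cm, ann, "aneu", "eu")}
        amp_called = self._calls(list(ann.amplified_genes("aneu")[:40]))
        cmap = ann.category_map()
        r1, _ = filter_amplified_calls(amp_called, enr, cmap)
        r2, removed2 = filter_amplified_calls(r1, enr, cmap)
        assert removed2.empty
        pd.testing.assert_frame_equal(r1, r2)

    def test_module_members_removed_non_members_retained(self, trans_sim):
        cm, ann, gt = trans_sim
        enr = {"aneu": strain_enrichment(cm, ann, "aneu", "eu")}
        assert (enr["aneu"]["pvalue"] < 0.0004).any()
        amp = ann.amplified_genes("aneu")
        module_amp = [g for g in amp if gt.genes.loc[g, "module"] == "stress_mod"]
        clean_amp = [g for g in amp if gt.genes.loc[g, "module"] == ""][:20]
        calls = self._calls(module_amp + clean_amp)
        revised, removed = filter_amplified_calls(calls, enr, ann.category_map())
        assert set(module_amp) <= set(removed.index)
        # genes outside any enriched category survive
        enriched_cats = set(
            enr["aneu"].index[enr["aneu"]["pvalue"] < 0.0004]
        )
        survivors_expected = [
            g for g in clean_amp
            if not (ann.table.loc[g, "categories"] & enriched_cats)
        ]
        assert set(survivors_expected) <= set(revised.index)

    def test_anti_monotone_in_threshold(self, trans_sim):
        cm, ann, gt = trans_sim
        enr = {"aneu": strain_enrichment(cm, ann, "aneu", "eu")}
        calls = self._calls(list(ann.amplified_genes("aneu")))
        cmap = ann.category_map()
        sizes = []
        for p in (1e-8, 0.0004, 0.05):
            revised, _ = filter_amplified_calls(calls, enr, cmap, p_threshold=p)
            sizes.append(len(revised))
        assert sizes == sorted(sizes, reverse=True)


class TestPartition:
    def _calls(self, effects):
        return pd.DataFrame(
            {"effect_size": effects, "strain": "A"},
            index=pd.Index([f"g{i}" for i in range(len(effects))], name="gene_id"),
        )

    def test_nine_split_evenly(self):
        tert = partition_by_effect(self._calls(np.linspace(-1, -0.1, 9)))
        assert tert.value_counts().to_dict() == {
            "top_third": 3, "middle_third": 3, "bottom_third": 3
        }

    def test_ten_extra_goes_to_top(self):
        tert = partition_by_effect(self._calls(np.linspace(-1, -0.1, 10)))
        counts = tert.value_counts()
        assert counts["top_third"] == 4
        assert counts["middle_third"] == 3 and counts["bottom_third"] == 3

    def test_strongest_reduction_is_top(self):
        calls = self._calls([-0.1, -1.0, -0.5])
        tert = partition_by_effect(calls)
        assert tert[calls["effect_size"].idxmin()] == "top_third"
        assert set(tert[calls["effect_size"] == -1.0]) == {"top_third"}

    def test_union_covers_exactly_once(self):
        calls = self._calls(np.linspace(-2, -0.1, 17))
        tert = partition_by_effect(calls)
        assert sorted(tert.index) == sorted(calls.index)
        assert tert.notna().all()

    def test_fewer_than_bins(self):
        tert = partition_by_effect(self._calls([-0.5, -0.2]))
        assert len(tert) == 2
        assert tert.notna().all()

    def test_deterministic_tie_break(self):
        calls = self._calls([-0.5] * 6)
        t1 = partition_by_effect(calls)
        t2 = partition_by_effect(calls.iloc[::-1])
        pd.testing.assert_series_equal(t1.sort_index(), t2.sort_index())
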