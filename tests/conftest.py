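import numpy as np
import pandas as pd
import pytest

import aneudose as ad


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three genes, two strains (RNA+DNA each), hand-checkable."""
    counts = pd.DataFrame(
        {
            "eu_RNA_r1": [100, 50, 200],
            "aneu_RNA_r1": [200, 50, 100],
            "eu_DNA_r1": [100, 100, 100],
            "aneu_DNA_r1": [200, 100, 100],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    samples = ad.io_normalize.samples_frame(
        [
            ad.SampleMeta("eu_RNA_r1", "eu", "RNA", 1, spike_total=1e5, cells_counted=1e6),
            ad.SampleMeta("aneu_RNA_r1", "aneu", "RNA", 1, spike_total=1e5, cells_counted=1e6),
            ad.SampleMeta("eu_DNA_r1", "eu", "DNA", 1, spike_total=1e5, cells_counted=1e6),
            ad.SampleMeta("aneu_DNA_r1", "aneu", "DNA", 1, spike_total=1e5, cells_counted=1e6),
        ]
    )
    cm = ad.CountMatrix(counts, samples)
    ann = ad.GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["chr01", "chr02", "chr02"],
                "length_bp": [1000, 2000, 1000],
                "amplified_in": [frozenset({"aneu"}), frozenset(), frozenset()],
                "categories": [frozenset(), frozenset({"catA"}), frozenset()],
            },
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
    )
    return cm, ann


@pytest.fixture(scope="session")
def pair_sim():
    """Pair-design simulation at study-like conditions (two strain pairs,
    15% fully compensated amplified genes)."""
    cfg = ad.default_pair_config(
        n_genes=2000,
        n_strain_pairs=2,
        class_fractions={"proportional": 0.85, "compensated_flat": 0.15},
        seed=42,
    )
    cm, ann, gt = ad.simulate_pair(cfg)
    abund = ad.rpkm_normalize(cm, ann, exclude_chromosomes=["chr01"])
    rt = ad.log2_ratios(abund, cm.samples, ad.pair_comparisons(cm))
    return cm, ann, gt, rt


@pytest.fixture(scope="session")
def panel_sim():
    """Panel-design simulation at default class fractions."""
    cfg = ad.default_panel_config(n_genes=2000, seed=42)
    cm, ann, gt = ad.simulate_panel(cfg)
    abund = ad.rpkm_normalize(cm, ann, exclude_chromosomes=["chr01"])
    rt = ad.log2_ratios(abund, cm.samples, ad.panel_pairs(cm))
    return cm, ann, gt, rt


@pytest.fixture(scope="session")
def panel_fit(panel_sim):
    cm, ann, gt, rt = panel_sim
    dp = ad.build_dosage_points(rt, ann)
    fit = ad.MixtureLinearRegression(random_state=0).fit(dp)
    return dp, fit, gt


TRUTH_TO_MLR = {
    "proportional": "class1_proportional",
    "compensated_flat": "class2_flat",
    "sub_proportional": "class3a_sub",
    "super_proportional": "class3b_super",
}


@pytest.fixture(scope="session")
def truth_to_mlr():
    return dict(TRUTH_TO_MLR)
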