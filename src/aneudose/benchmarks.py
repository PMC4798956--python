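"""Study-condition benchmark runs used for validation.

Each function simulates data at the conditions the analyses were designed
for (2,000-gene genomes, a quarter of genes on the amplified chromosome,
replicate log2-ratio SD 0.2, copy ratio 2, panel copy states 1/1.5/2) and
measures how well the corresponding stage recovers the known ground
truth.  They are consumed by the validation test-suite and by the
repository's acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_normalize import log2_ratios, rpkm_normalize
from .mlr_model import (
    DosagePoints,
    MixtureLinearRegression,
    build_dosage_points,
    compare_null_proportions,
    conditional_fdr,
    estimate_pi0,
    lrt_proportionality,
)
from .synthetic import (
    default_pair_config,
    default_panel_config,
    pair_comparisons,
    panel_pairs,
    simulate_pair,
    simulate_panel,
)
from .threshold_caller import (
    ThresholdSpec,
    call_lower_expressed,
    difference_matrix,
    permutation_fdr,
)

TRUTH_TO_MLR = {
    "proportional": "class1_proportional",
    "compensated_flat": "class2_flat",
    "sub_proportional": "class3a_sub",
    "super_proportional": "class3b_super",
}

PI_TRUTH = {
    "class1_proportional": 0.75,
    "class2_flat": 0.10,
    "class3a_sub": 0.10,
    "class3b_super": 0.05,
}

X_PANEL = np.array([0.0, np.log2(1.5), 1.0])


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s & 0x7FFFFFFF)
        for s in np.random.SeedSequence(seed).generate_state(n)
    ]


def _pair_ratio_table(seed: int):
    cfg = default_pair_config(
        n_genes=2000,
        n_strain_pairs=2,
        class_fractions={"proportional": 0.85, "compensated_flat": 0.15},
        seed=seed,
    )
    cm, ann, gt = simulate_pair(cfg)
    abund = rpkm_normalize(cm, ann, exclude_chromosomes=[cfg.amplified_chromosome])
    rt = log2_ratios(abund, cm.samples, pair_comparisons(cm))
    return cm, ann, gt, rt


def panel_ratio_table(seed: int):
    cfg = default_panel_config(n_genes=2000, seed=seed)
    cm, ann, gt = simulate_panel(cfg)
    abund = rpkm_normalize(cm, ann, exclude_chromosomes=[cfg.amplified_chromosome])
    rt = log2_ratios(abund, cm.samples, panel_pairs(cm))
    return cm, ann, gt, rt


def threshold_recovery(seed: int) -> dict:
    """Sensitivity for compensated genes and called share of amplified
    genes under the four-replicate intersection rule (two strain pairs,
    15% fully compensated)."""
    cm, ann, gt, rt = _pair_ratio_table(seed)
    cs = call_lower_expressed(rt, ann, ThresholdSpec(k_sd=1.0))
    flat = set(gt.genes_in_class("compensated_flat"))
    called = set(cs.called_genes)
    sensitivity = len(called & flat) / len(flat)
    share = len(called) / cs.n_assessed
    return {
        "sensitivity": sensitivity,
        "called_share": share,
        "n_assessed": cs.n_assessed,
        "n_called": len(called),
    }


def threshold_fdr_calibration(seed: int, n_seeds: int = 20, n_iter: int = 10000) -> dict:
    """Permutation-FDR estimate vs realized false-discovery proportion,
    averaged over independent simulations."""
    gaps, ests, fdps = [], [], []
    for s in _child_seeds(seed, n_seeds):
        cm, ann, gt, rt = _pair_ratio_table(s)
        cs = call_lower_expressed(rt, ann, ThresholdSpec(k_sd=1.0))
        called = cs.called_genes
        if len(called) == 0:
            continue
        fdp = float(
            (gt.class_labels.loc[called] == "proportional").mean()
        )
        perm = permutation_fdr(difference_matrix(rt, cs), n_iter=n_iter, seed=s)
        ests.append(perm.fdr)
        fdps.append(fdp)
        gaps.append(perm.fdr - fdp)
    return {
        "mean_gap": float(np.mean(gaps)),
        "mean_abs_gap": float(np.mean(np.abs(gaps))),
        "mean_estimate": float(np.mean(ests)),
        "mean_fdp": float(np.mean(fdps)),
        "n_seeds": len(gaps),
    }


def permutation_null_oracle(seed: int, n_genes: int = 1600, n_iter: int = 10000) -> dict:
    """Symmetric null d-values, 4 independent replicate columns: the mean
    permuted all-negative count must sit at G/16 (exactly half of each
    column is negative by construction)."""
    rng = np.random.default_rng(seed)
    half = rng.uniform(0.1, 1.0, size=(n_genes // 2, 4))
    d = np.concatenate([half, -half], axis=0)
    for j in range(4):
        rng.shuffle(d[:, j])
    res = permutation_fdr(d, n_iter=n_iter, seed=seed)
    expected = n_genes / 16.0
    se = float(res.null_counts.std(ddof=1) / np.sqrt(n_iter))
    return {
        "mean_null_count": res.mean_null_count,
        "expected": expected,
        "ratio": res.mean_null_count / expected,
        "se": se,
        "n_genes": n_genes,
    }


def mlr_recovery(seed: int) -> dict:
    """Mixture fit on a 2,000-gene panel simulation: recovered mixing
    proportions, the shared sub-proportional slope, and the
    maximum-posterior label accuracy against ground truth."""
    cm, ann, gt, rt = panel_ratio_table(seed)
    dp = build_dosage_points(rt, ann)
    fit = MixtureLinearRegression(random_state=seed).fit(dp)
    truth = gt.class_labels.reindex(fit.gene_ids_).map(TRUTH_TO_MLR)
    accuracy = float((fit.labels_ == truth).mean())
    pi_err = {
        k: float(abs(fit.weights_[k] - v)) for k, v in PI_TRUTH.items()
    }
    slope = [c.slope for c in fit.components_ if c.label == "class3a_sub"][0]
    trace = fit.loglik_trace_
    monotone = bool(
        np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]) - 1e-8)
    )
    called = fit.labels_.index[fit.labels_ == "class3a_sub"]
    realized = float((truth.loc[called] != "class3a_sub").mean()) if len(called) else np.nan
    return {
        "fit": fit,
        "truth": truth,
        "accuracy": accuracy,
        "pi_abs_error": pi_err,
        "pi_max_abs_error": max(pi_err.values()),
        "class3a_slope": float(slope),
        "loglik_monotone": monotone,
        "class3a_conditional_fdr": conditional_fdr(fit, "class3a_sub"),
        "class3a_realized_fdp": realized,
        "n_genes_fit": int(dp.n_genes),
    }


def conditional_fdr_calibration(seed: int, n_seeds: int = 10) -> dict:
    gaps, ests, reals = [], [], []
    for s in _child_seeds(seed, n_seeds):
        res = mlr_recovery(s)
        if np.isnan(res["class3a_realized_fdp"]):
            continue
        ests.append(res["class3a_conditional_fdr"])
        reals.append(res["class3a_realized_fdp"])
        gaps.append(ests[-1] - reals[-1])
    return {
        "mean_gap": float(np.mean(gaps)),
        "mean_estimate": float(np.mean(ests)),
        "mean_realized": float(np.mean(reals)),
        "n_seeds": len(gaps),
    }


def _null_points(seed: int, n_genes: int, flat_fraction: float = 0.0) -> tuple[DosagePoints, int]:
    """y = b*x + N(0, 0.2) over the panel design (3 strains x 3 reps);
    a ``flat_fraction`` of genes gets b=0 (strong alternatives), the rest
    the proportional null b=1."""
    rng = np.random.default_rng(seed)
    n_alt = int(round(n_genes * flat_fraction))
    slopes = np.concatenate([np.ones(n_genes - n_alt), np.zeros(n_alt)])
    x = np.tile(np.repeat(X_PANEL, 3), n_genes)
    b = np.repeat(slopes, 9)
    y = b * x + rng.normal(0.0, 0.2, size=9 * n_genes)
    gid = np.repeat(np.arange(n_genes), 9)
    ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    return DosagePoints(x, y, gid, ids), n_genes - n_alt


def lrt_type1(seed: int, n_genes: int = 5000, alpha: float = 0.05) -> dict:
    dp, _ = _null_points(seed, n_genes)
    res = lrt_proportionality(dp)
    rate = float((res["pvalue"] < alpha).mean())
    from scipy import stats

    lo = float(stats.binom.ppf(0.025, n_genes, alpha) / n_genes)
    hi = float(stats.binom.ppf(0.975, n_genes, alpha) / n_genes)
    return {"rate": rate, "lo": lo, "hi": hi, "n_genes": n_genes}


def pi0_mixture(seed: int, n_genes: int = 5000) -> dict:
    dp, n_null = _null_points(seed, n_genes, flat_fraction=0.5)
    res = lrt_proportionality(dp)
    pi0 = estimate_pi0(res["pvalue"]).pi0
    true_pi0 = n_null / n_genes
    return {"pi0": float(pi0), "true_pi0": true_pi0,
            "abs_error": float(abs(pi0 - true_pi0)), "n_genes": n_genes}


def mlr_pi0_agreement(seed: int, n_seeds: int = 10) -> dict:
    """Mixture non-proportional share vs 1 - pi0 from the per-gene LRT on
    default panel simulations."""
    diffs, mlr_np, lrt_nn = [], [], []
    for s in _child_seeds(seed, n_seeds):
        cm, ann, gt, rt = panel_ratio_table(s)
        dp = build_dosage_points(rt, ann)
        fit = MixtureLinearRegression(random_state=s).fit(dp)
        lrt = lrt_proportionality(dp)
        rep = compare_null_proportions(fit, lrt)
        diffs.append(rep.difference)
        mlr_np.append(rep.mlr_nonproportional)
        lrt_nn.append(rep.lrt_nonnull)
    return {
        "mean_difference": float(np.mean(diffs)),
        "mean_mlr_nonproportional": float(np.mean(mlr_np)),
        "mean_lrt_nonnull": float(np.mean(lrt_nn)),
        "n_seeds": n_seeds,
    }
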