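"""Indirect-response filter and effect-size partition.

Some amplified genes flagged as lower-expressed belong to functional
programs that the aneuploid state represses genome-wide (e.g. a
mitochondrial or translation response) — their reduced expression is a
trans effect, not dosage compensation.  The filter finds, per strain,
unamplified genes with significantly reduced expression, the functional
categories enriched among them (hypergeometric, p < 0.0004), and removes
amplified calls that fall in any category enriched in their own strain.
Surviving calls are ranked by effect size (mean log2 mRNA ratio minus
log2 DNA ratio) and split into thirds; the "top third" holds the
strongest reductions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_normalize import (
    CategoryMap,
    CountMatrix,
    GeneAnnotation,
    RatioTable,
    rpkm_normalize,
)

logger = logging.getLogger(__name__)

DE_FDR_DEFAULT = 0.01
ENRICH_P_DEFAULT = 0.0004
MODERATION_PRIOR_DF = 10.0


def call_de_unamplified(
    cm: CountMatrix,
    ann: GeneAnnotation,
    strain: str,
    ref_strain: str,
    method: str = "ratio_t",
    de_table: pd.DataFrame | str | None = None,
) -> pd.DataFrame:
    """Differential expression of unamplified genes, aneuploid versus
    euploid.

    ``ratio_t`` is the built-in stand-in: per gene, a variance-moderated
    one-sample t-test of the replicate log2 RPKM ratios against 0
    (per-gene variances are shrunk toward the genome-wide mean with a
    prior of ``MODERATION_PRIOR_DF`` degrees of freedom, the standard
    remedy for 2-3 replicates), BH-adjusted; needs >= 2 replicate pairs.
    ``import`` takes an externally produced table
    unchanged (columns gene_id, log2fc, pvalue, fdr) so results from a
    count-based DE fit can be dropped in.  Downstream selection is
    always FDR < 0.01 and negative mean log2 fold-change.
    """
    genes = ann.unamplified_genes(strain)
    if method == "import":
        if de_table is None:
            raise ValueError("method='import' requires de_table")
        if not isinstance(de_table, pd.DataFrame):
            de_table = pd.read_csv(de_table, sep="\t")
        de = de_table.set_index("gene_id") if "gene_id" in de_table else de_table
        return de.loc[de.index.intersection(genes), ["log2fc", "pvalue", "fdr"]]
    if method != "ratio_t":
        raise ValueError("method must be 'ratio_t' or 'import'")

    test = cm.samples_for(strain, "RNA")
    ref = cm.samples_for(ref_strain, "RNA")
    n_pairs = min(len(test), len(ref))
    if n_pairs < 2:
        raise ValueError(
            "ratio_t needs >=2 RNA replicates per condition; "
            "use method='import' with an external DE table"
        )
    abund = rpkm_normalize(cm, ann)
    ratios = []
    for t, r in zip(test[:n_pairs], ref[:n_pairs]):
        a, b = abund[t], abund[r]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(np.log2(a / b))
    mat = pd.concat(ratios, axis=1).loc[genes]
    mat = mat.replace([np.inf, -np.inf], np.nan).dropna()
    log2fc = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    d_resid = mat.shape[1] - 1
    s0 = float(var.mean())
    var_mod = (MODERATION_PRIOR_DF * s0 + d_resid * var) / (
        MODERATION_PRIOR_DF + d_resid
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / np.sqrt(var_mod / mat.shape[1])
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(tstat), MODERATION_PRIOR_DF + d_resid),
        index=mat.index,
    )
    # zero-variance, zero-change rows carry no evidence
    p = p.fillna(1.0)
    fdr = multipletests(p.to_numpy(), method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "fdr": fdr}, index=mat.index
    )


def select_lower_expressed(
    de: pd.DataFrame, fdr_threshold: float = DE_FDR_DEFAULT
) -> pd.Index:
    """Unamplified genes taken as 'lower expressed': FDR below the
    threshold and negative mean log2 fold-change."""
    mask = (de["fdr"] < fdr_threshold) & (de["log2fc"] < 0)
    return de.index[mask]


def enrich_categories(
    query_genes: Iterable[str],
    category_map: CategoryMap,
    universe: Iterable[str],
    exclude_localization: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each category in the
    query, within the universe.  Categories flagged as localization are
    skipped when ``exclude_localization``; an empty query yields an
    empty result."""
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    query = set(query_genes)
    if not query <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    M = len(universe)
    nq = len(query)
    if nq == 0:
        return pd.DataFrame(
            columns=["category", "overlap", "category_size", "query_size",
                     "universe_size", "pvalue"]
        ).set_index("category")
    for cat, members in category_map.genes.items():
        if exclude_localization and cat in category_map.localization:
            continue
        in_universe = universe.intersection(list(members))
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & set(in_universe))
        p = float(stats.hypergeom.sf(k - 1, M, K, nq))
        rows.append(
            {"category": cat, "overlap": k, "category_size": K,
             "query_size": nq, "universe_size": M, "pvalue": p}
        )
    out = pd.DataFrame(
        rows, columns=["category", "overlap", "category_size", "query_size",
                       "universe_size", "pvalue"]
    )
    return out.set_index("category").sort_values("pvalue")


def strain_enrichment(
    cm: CountMatrix,
    ann: GeneAnnotation,
    strain: str,
    ref_strain: str,
    category_map: CategoryMap | None = None,
    fdr_threshold: float = DE_FDR_DEFAULT,
    de_method: str = "ratio_t",
    de_table=None,
) -> pd.DataFrame:
    """DE on unamplified genes of one strain, then category enrichment of
    the lower-expressed set.  Universe = unamplified genes assessed in
    that strain."""
    de = call_de_unamplified(cm, ann, strain, ref_strain, de_method, de_table)
    lower = select_lower_expressed(de, fdr_threshold)
    if category_map is None:
        category_map = ann.category_map()
    return enrich_categories(lower, category_map, de.index)


def filter_amplified_calls(
    calls: pd.DataFrame,
    enrichment: Mapping[str, pd.DataFrame],
    category_map: CategoryMap,
    p_threshold: float = ENRICH_P_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove called amplified genes that belong to any category enriched
    (p < threshold) among down-regulated unamplified genes of their own
    strain.

    ``calls`` is gene-indexed with a ``strain`` column; ``enrichment``
    maps strain -> enrichment table.  Returns (revised_calls, removed)
    with the removal fraction in ``revised.attrs['removal_fraction']``.
    Genes without category annotation cannot match and are retained.
    """
    if "strain" not in calls.columns:
        raise ValueError("calls must carry a 'strain' column")
    enriched_by_strain = {
        s: set(tab.index[tab["pvalue"] < p_threshold])
        for s, tab in enrichment.items()
    }
    removed_mask = pd.Series(False, index=calls.index)
    hit_category = pd.Series("", index=calls.index)
    for gene, strain in calls["strain"].items():
        cats = enriched_by_strain.get(strain, set())
        if not cats:
            continue
        mine = category_map.categories_of(gene)
        hit = mine & cats
        if hit:
            removed_mask.loc[gene] = True
            hit_category.loc[gene] = ";".join(sorted(hit))
    revised = calls[~removed_mask].copy()
    removed = calls[removed_mask].copy()
    removed["enriched_category"] = hit_category[removed_mask]
    frac = float(removed_mask.mean()) if len(calls) else 0.0
    revised.attrs["removal_fraction"] = frac
    logger.info(
        "indirect-response filter removed %d/%d calls (%.1f%%)",
        len(removed), len(calls), 100 * frac,
    )
    return revised, removed


def partition_by_effect(
    calls: pd.DataFrame, n_bins: int = 3
) -> pd.Series:
    """Rank calls by effect size (most negative first = strongest
    reduction) and split into near-equal bins; extra genes go to the
    strongest bins, ties break by gene_id for determinism.  With three
    bins the labels are top/middle/bottom third."""
    if "effect_size" not in calls.columns:
        raise ValueError("calls must carry an 'effect_size' column")
    n = len(calls)
    order = calls.assign(_gid=calls.index).sort_values(["effect_size", "_gid"])
    if n < n_bins:
        logger.warning("fewer calls (%d) than bins (%d): one gene per bin", n, n_bins)
        sizes = [1] * n
    else:
        base, extra = divmod(n, n_bins)
        sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    if n_bins == 3:
        names = ["top_third", "middle_third", "bottom_third"]
    else:
        names = [f"bin{i+1}" for i in range(n_bins)]
    labels = []
    for name, size in zip(names, sizes):
        labels.extend([name] * size)
    return pd.Series(labels, index=order.index, name="effect_tertile").reindex(
        calls.index
    )
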