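"""Population CNV summaries and buffering scores for gene groups.

Inputs are a population CNV survey (per gene, the number of surveyed
strains — 103 in the original survey — carrying a duplication) and a
per-gene expression-constraint value Vg/Vm (genetic over mutational
variance; low values = strong constraint).  The CNV fraction of a gene
group is the share of genes duplicated in at least ``min_strains``
strains; the buffering score of a gene with CNV is its duplication count
divided by Vg/Vm, so high scores flag genes that vary in copy number
despite constrained expression — the signature expected of genes whose
dosage is buffered at the mRNA level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _check_records(records: pd.DataFrame) -> None:
    for col in ("n_strains_amplified", "vg_vm"):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")


def cnv_fraction(
    records: pd.DataFrame,
    group: Iterable[str] | None = None,
    min_strains: int = 3,
) -> float:
    """Fraction of genes in the group duplicated in at least
    ``min_strains`` of the surveyed strains."""
    _check_records(records)
    sub = records if group is None else records.loc[pd.Index(group)]
    if len(sub) == 0:
        raise ValueError("empty gene group")
    return float((sub["n_strains_amplified"] >= min_strains).mean())


def buffering_scores(records: pd.DataFrame) -> pd.Series:
    """Buffering score = duplication strain count / (Vg/Vm), restricted
    to genes with CNV (>= 1 strain); non-positive Vg/Vm excluded with a
    warning."""
    _check_records(records)
    with_cnv = records[records["n_strains_amplified"] >= 1]
    bad = with_cnv["vg_vm"] <= 0
    if bad.any():
        logger.warning(
            "%d gene(s) with non-positive Vg/Vm excluded from buffering scores",
            int(bad.sum()),
        )
    ok = with_cnv[~bad]
    return (ok["n_strains_amplified"] / ok["vg_vm"]).rename("buffering_score")


@dataclass
class GroupComparison:
    pvalue: float
    direction: int          # sign of median(a) - median(b)
    test: str
    n_a: int
    n_b: int


def compare_groups(
    scores_a: pd.Series | np.ndarray,
    scores_b: pd.Series | np.ndarray,
    test: str = "rank_sum",
) -> GroupComparison:
    """Two-sided comparison of score distributions; the default is the
    Wilcoxon rank-sum test (the test choice is declared in the output)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if test != "rank_sum":
        raise ValueError("only 'rank_sum' is supported for score groups")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    direction = int(np.sign(np.median(a) - np.median(b)))
    return GroupComparison(float(res.pvalue), direction, "wilcoxon_rank_sum",
                           len(a), len(b))


def compare_fractions(
    k_a: int, n_a: int, k_b: int, n_b: int
) -> GroupComparison:
    """Fisher's exact test for two CNV fractions."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 genes")
    _, p = stats.fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    direction = int(np.sign(k_a / n_a - k_b / n_b))
    return GroupComparison(float(p), direction, "fisher_exact", n_a, n_b)


def holdout_robustness(
    records: pd.DataFrame,
    partition: pd.Series,
    analysis: Callable[[pd.DataFrame], float],
) -> pd.DataFrame:
    """Re-run an analysis with each partition cell (chromosome or
    functional category) held out.

    ``partition`` maps gene -> cell and must cover all record genes.
    ``analysis`` receives the reduced records and returns a signed
    statistic; a cell whose removal empties the analysis (the callable
    raises ValueError) is flagged rather than failed.  One row per cell.
    """
    if not set(records.index).issubset(set(partition.index)):
        raise ValueError("partition must cover all genes in records")
    rows = []
    for cell in pd.unique(partition.loc[records.index]):
        keep = records.index[partition.loc[records.index] != cell]
        sub = records.loc[keep]
        try:
            value = float(analysis(sub))
            flagged = False
        except ValueError as err:
            logger.warning("holdout %r flagged: %s", cell, err)
            value, flagged = float("nan"), True
        rows.append({"holdout": cell, "value": value, "flagged": flagged})
    return pd.DataFrame(rows).set_index("holdout")


def evolution_report(
    records: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    min_strains: int = 3,
) -> pd.DataFrame:
    """Per-group CNV fraction and median buffering score with two-sided
    tests against a reference group (e.g. proportionately expressed
    amplified genes)."""
    _check_records(records)
    groups = groups.loc[groups.index.intersection(records.index)]
    scores = buffering_scores(records)
    ref_genes = groups.index[groups == reference_group]
    if len(ref_genes) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_scores = scores.reindex(ref_genes).dropna()
    ref_k = int((records.loc[ref_genes, "n_strains_amplified"] >= min_strains).sum())
    rows = []
    for g in pd.unique(groups):
        genes = groups.index[groups == g]
        frac = cnv_fraction(records, genes, min_strains)
        g_scores = scores.reindex(genes).dropna()
        row = {
            "group": g,
            "n_genes": len(genes),
            "cnv_fraction": frac,
            "n_with_cnv": len(g_scores),
            "median_buffering": float(g_scores.median()) if len(g_scores) else np.nan,
        }
        if g != reference_group:
            k = int((records.loc[genes, "n_strains_amplified"] >= min_strains).sum())
            row["fraction_pvalue"] = compare_fractions(
                k, len(genes), ref_k, len(ref_genes)
            ).pvalue
            if len(g_scores) >= 2 and len(ref_scores) >= 2:
                cmp = compare_groups(g_scores, ref_scores)
                row["buffering_pvalue"] = cmp.pvalue
                row["buffering_direction"] = cmp.direction
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
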