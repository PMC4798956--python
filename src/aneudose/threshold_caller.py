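"""Gene-specific threshold calls and permutation false-discovery estimate.

A gene on the amplified chromosome is flagged as expressed lower than
expected when its log2 mRNA ratio (aneuploid vs euploid) falls below a
gene-specific cutoff in *every* biological replicate of every listed
strain comparison.  The cutoff is that gene's measured log2 DNA ratio
minus ``k_sd`` standard deviations of the DNA-ratio spread across the
amplified chromosome (k_sd=1 by default; k_sd=3 is the stringent
variant).  Comparing mRNA ratios to measured, not theoretical, DNA ratios
absorbs gene-specific sequencing biases while the SD term absorbs
measurement noise.

The false-discovery rate of the rule is estimated by permutation: the
per-replicate differences (mRNA ratio minus threshold) are permuted over
gene labels independently within each replicate column, and the average
number of all-negative genes over the permutations, divided by the
observed call count, is the FDR estimate.  Some true positives survive
permutation, so the estimate is conservatively biased upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_normalize import GeneAnnotation, RatioTable

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSpec:
    """Threshold rule parameters.

    ``sd_chr`` maps comparison_id -> SD of DNA log2 ratios on the
    affected chromosome; when absent it is computed from the data.
    ``require_all_replicates`` is the four-replicate style rule (a call
    needs every replicate of every comparison below threshold); it is
    always on in the published analyses.
    """

    k_sd: float = 1.0
    sd_chr: dict = field(default_factory=dict)
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        for comp, sd in self.sd_chr.items():
            if sd <= 0:
                raise ValueError(f"sd_chr for {comp!r} must be > 0")


@dataclass
class ThresholdCallSet:
    """Result of the threshold rule over one or more comparisons.

    ``calls`` is indexed by gene with columns called,
    n_replicates_below, n_replicates, effect_size, strain.  The effect
    size is the mean log2 mRNA ratio minus the log2 DNA ratio (most
    negative = strongest reduction).  ``not_assessed`` lists genes that
    lacked a complete set of measurements across the comparisons.
    """

    calls: pd.DataFrame
    thresholds: pd.DataFrame  # gene_id, comparison_id, threshold
    spec: ThresholdSpec
    comparison_ids: list
    not_assessed: pd.Index
    fdr_estimate: float | None = None
    null_counts: np.ndarray | None = None

    @property
    def called_genes(self) -> pd.Index:
        return self.calls.index[self.calls["called"]]

    @property
    def n_assessed(self) -> int:
        return len(self.calls)


@dataclass
class PermutationFDR:
    fdr: float
    mean_null_count: float
    null_counts: np.ndarray
    observed_count: int
    n_iter: int
    undefined: bool = False


def chromosome_sd(
    rt: RatioTable,
    ann: GeneAnnotation,
    comparison_id: str,
    chromosome: str | None = None,
) -> float:
    """Sample SD (n-1 denominator) of log2 DNA ratios over the amplified
    genes of the affected chromosome in one comparison."""
    strain = rt.test_strain(comparison_id)
    amp = ann.amplified_genes(strain)
    if chromosome is not None:
        amp = amp.intersection(ann.genes_on(chromosome))
    dna = rt.dna(comparison_id)
    vals = dna.reindex(amp).dropna()
    if len(vals) < 2:
        raise ValueError(
            f"comparison {comparison_id!r}: need >=2 amplified genes with "
            f"DNA ratios, got {len(vals)}"
        )
    sd = float(vals.std(ddof=1))
    if sd <= 0:
        raise ValueError(
            f"comparison {comparison_id!r}: degenerate (constant) DNA ratios"
        )
    return sd


def _resolve_sd(
    rt: RatioTable, ann: GeneAnnotation, comparison_id: str, spec: ThresholdSpec
) -> float:
    if comparison_id in spec.sd_chr:
        return spec.sd_chr[comparison_id]
    return chromosome_sd(rt, ann, comparison_id)


def gene_thresholds(
    rt: RatioTable,
    ann: GeneAnnotation,
    comparison_id: str,
    spec: ThresholdSpec,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Per-gene cutoff: log2 DNA ratio minus k_sd * chromosome SD.

    Defaults to the amplified genes of the comparison's test strain;
    pass ``genes`` for the matched unamplified-gene control.  Genes
    without a DNA ratio in the comparison are dropped with a warning.
    """
    if genes is None:
        genes = ann.amplified_genes(rt.test_strain(comparison_id))
    sd = _resolve_sd(rt, ann, comparison_id, spec)
    dna = rt.dna(comparison_id).reindex(genes)
    missing = dna.index[dna.isna()]
    if len(missing):
        logger.warning(
            "comparison %s: %d gene(s) without DNA ratio dropped",
            comparison_id,
            len(missing),
        )
    thr = (dna.dropna() - spec.k_sd * sd).rename("threshold")
    return thr


def _call_core(
    rt: RatioTable,
    thresholds: Mapping[str, pd.Series],
    spec: ThresholdSpec,
) -> ThresholdCallSet:
    comparisons = list(thresholds)
    per_comp_mrna = {c: rt.mrna(c) for c in comparisons}
    assessed: pd.Index | None = None
    union: pd.Index = pd.Index([])
    for c in comparisons:
        present = thresholds[c].index.intersection(
            per_comp_mrna[c].dropna(how="any").index
        )
        union = union.union(thresholds[c].index)
        assessed = present if assessed is None else assessed.intersection(present)
    assessed = pd.Index([]) if assessed is None else assessed
    not_assessed = union.difference(assessed)
    if len(not_assessed):
        logger.info(
            "%d gene(s) not assessed (missing in >=1 comparison)", len(not_assessed)
        )

    thr_rows = []
    n_below = pd.Series(0, index=assessed)
    n_total = pd.Series(0, index=assessed)
    effect_parts = []
    for c in comparisons:
        thr = thresholds[c].reindex(assessed)
        mrna = per_comp_mrna[c].reindex(assessed)
        below = mrna.lt(thr, axis=0)  # strict: ties are not called
        n_below += below.sum(axis=1)
        n_total += mrna.notna().sum(axis=1)
        dna = rt.dna(c).reindex(assessed)
        effect_parts.append(mrna.mean(axis=1) - dna)
        thr_rows.append(
            pd.DataFrame(
                {"gene_id": thr.index, "comparison_id": c, "threshold": thr.to_numpy()}
            )
        )
    called = (n_below == n_total) & (n_total > 0)
    effect = pd.concat(effect_parts, axis=1).mean(axis=1)

    strains = {rt.test_strain(c) for c in comparisons}
    strain = strains.pop() if len(strains) == 1 else "+".join(sorted(strains | set()))
    calls = pd.DataFrame(
        {
            "called": called,
            "n_replicates_below": n_below,
            "n_replicates": n_total,
            "effect_size": effect,
            "strain": strain,
        },
        index=assessed,
    )
    calls.index.name = "gene_id"
    return ThresholdCallSet(
        calls=calls,
        thresholds=pd.concat(thr_rows, ignore_index=True)
        if thr_rows
        else pd.DataFrame(columns=["gene_id", "comparison_id", "threshold"]),
        spec=spec,
        comparison_ids=comparisons,
        not_assessed=not_assessed,
    )


def call_lower_expressed(
    rt: RatioTable,
    ann: GeneAnnotation,
    spec: ThresholdSpec,
    comparisons: Sequence[str] | None = None,
) -> ThresholdCallSet:
    """Threshold calls on amplified genes: called iff the log2 mRNA ratio
    is below the gene-specific cutoff in every replicate of every listed
    comparison (the four-replicate rule when two duplicate comparisons
    are intersected)."""
    if comparisons is None:
        comparisons = rt.comparison_ids
    thresholds = {
        c: gene_thresholds(rt, ann, c, spec) for c in comparisons
    }
    return _call_core(rt, thresholds, spec)


def matched_unamplified_calls(
    rt: RatioTable,
    ann: GeneAnnotation,
    spec: ThresholdSpec,
    comparisons: Sequence[str] | None = None,
) -> ThresholdCallSet:
    """Identical rule applied to unamplified genes, as a matched control:
    each gene's own DNA ratio (near 0) minus k_sd times the *amplified*
    chromosome's SD."""
    if comparisons is None:
        comparisons = rt.comparison_ids
    thresholds = {}
    for c in comparisons:
        strain = rt.test_strain(c)
        genes = ann.unamplified_genes(strain)
        sd = _resolve_sd(rt, ann, c, spec)
        sub = ThresholdSpec(spec.k_sd, {c: sd}, spec.require_all_replicates)
        thresholds[c] = gene_thresholds(rt, ann, c, sub, genes=genes)
    return _call_core(rt, thresholds, spec)


def difference_matrix(
    rt: RatioTable, call_set: ThresholdCallSet
) -> pd.DataFrame:
    """Genes x replicate-columns of d = log2 mRNA ratio - threshold for
    assessed genes; the input for the permutation FDR."""
    blocks = []
    thr = call_set.thresholds
    for c in call_set.comparison_ids:
        t = thr[thr["comparison_id"] == c].set_index("gene_id")["threshold"]
        mrna = rt.mrna(c).reindex(call_set.calls.index)
        d = mrna.sub(t.reindex(call_set.calls.index), axis=0)
        d.columns = [f"{c}:rep{r}" for r in d.columns]
        blocks.append(d)
    return pd.concat(blocks, axis=1)


def permutation_fdr(
    d: pd.DataFrame | np.ndarray,
    n_iter: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> PermutationFDR:
    """Permutation FDR: each replicate column of ``d`` is independently
    permuted over genes; the null call count is the number of genes with
    every permuted value negative.  FDR = mean null count over
    iterations / observed call count."""
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("d must be genes x replicate-columns")
    neg = arr < 0
    observed = int(neg.all(axis=1).sum())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_genes, n_cols = neg.shape
    acc = None
    for j in range(n_cols):
        tiled = np.tile(neg[:, j], (n_iter, 1))
        perm = rng.permuted(tiled, axis=1)
        acc = perm if acc is None else (acc & perm)
    null_counts = acc.sum(axis=1)
    mean_null = float(null_counts.mean())
    if observed == 0:
        logger.warning("no observed calls: permutation FDR undefined")
        return PermutationFDR(
            float("nan"), mean_null, null_counts, 0, n_iter, undefined=True
        )
    return PermutationFDR(
        mean_null / observed, mean_null, null_counts, observed, n_iter
    )


class ThresholdCaller(BaseEstimator):
    """Estimator wrapper: fit on a RatioTable + annotation, exposing the
    call set, effect sizes and permutation-FDR estimate as fitted
    attributes.

    Parameters
    ----------
    k_sd : SD multiplier of the gene-specific threshold (1 default,
        3 stringent).
    n_permutations : label permutations for the FDR estimate (0 skips it).
    random_state : seed for the permutations.
    """

    def __init__(
        self,
        k_sd: float = 1.0,
        n_permutations: int = 10000,
        random_state: int | None = None,
    ):
        self.k_sd = k_sd
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(
        self,
        ratio_table: RatioTable,
        annotation: GeneAnnotation,
        comparisons: Sequence[str] | None = None,
    ) -> "ThresholdCaller":
        spec = ThresholdSpec(k_sd=self.k_sd)
        cs = call_lower_expressed(ratio_table, annotation, spec, comparisons)
        if self.n_permutations:
            d = difference_matrix(ratio_table, cs)
            perm = permutation_fdr(
                d, n_iter=self.n_permutations, seed=self.random_state
            )
            cs.fdr_estimate = perm.fdr
            cs.null_counts = perm.null_counts
            self.permutation_ = perm
        self.call_set_ = cs
        self.calls_ = cs.calls
        self.thresholds_ = cs.thresholds
        self.fdr_estimate_ = cs.fdr_estimate
        self.called_genes_ = cs.called_genes
        return self

    def predict(self, ratio_table=None, annotation=None) -> pd.Series:
        """Boolean per-gene call of the fitted (or newly supplied) data."""
        if ratio_table is None:
            return self.calls_["called"]
        spec = ThresholdSpec(k_sd=self.k_sd)
        return call_lower_expressed(ratio_table, annotation, spec).calls["called"]


def write_calls(cs: ThresholdCallSet, path) -> None:
    out = cs.calls.copy()
    thr = (
        cs.thresholds.groupby("gene_id")["threshold"].mean().reindex(out.index)
    )
    out.insert(0, "threshold", thr)
    out.to_csv(path, sep="\t", index_label="gene_id")
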