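"""Mixture-of-linear-regressions dosage-response model and LRT cross-check.

For a panel of isogenic strains carrying 2-4 copies of one chromosome,
each gene g contributes points (x, y): x is the gene's log2 DNA ratio of
a panel strain versus the euploid and y the log2 mRNA ratio of one
replicate.  All replicate points of all genes are fit simultaneously by
a finite mixture of regression lines through the origin:

* class1_proportional — slope fixed at 1 (expression tracks dosage),
* class2_flat        — slope fixed at 0 (full compensation),
* class3a_sub        — shared free slope in (0,1) (partial compensation),
* class3b_super      — shared free slope > 1,
* outlier            — free intercept and slope with inflated variance,
  housing genes without a linear mRNA:DNA relationship.

EM alternates gene-level posteriors (product of normal densities of a
gene's points under each component) with weighted updates of the mixing
proportions, the free slopes (posterior-weighted least squares projected
into the class interval) and a shared noise SD.  Genes are classified by
maximum posterior with no effect-size cutoff, and each called class
carries a conditional FDR: the mean posterior probability of *not*
belonging to the class among its called genes.

An independent check fits per-gene ordinary least squares and tests the
null of proportional expression (intercept 0, slope 1) by a likelihood
ratio; the proportion of null genes is then estimated from the p-value
distribution (Storey-style pi0), to be compared with the mixture's
proportional share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .io_normalize import GeneAnnotation, RatioTable

logger = logging.getLogger(__name__)

OUTLIER_LABEL = "nonlinear_outlier"
PROPORTIONAL_LABEL = "class1_proportional"


@dataclass
class MLRComponent:
    """One regression line of the mixture.  Fixed parameters are never
    updated by EM; free slopes are projected into ``slope_bounds``."""

    label: str
    intercept: float = 0.0
    slope: float = 1.0
    fix_intercept: bool = True
    fix_slope: bool = True
    slope_bounds: tuple[float, float] = (-np.inf, np.inf)
    var_inflation: float = 1.0


def default_components(
    slope_margin: float = 0.01,
    outlier: bool = True,
    outlier_var_inflation: float = 5.0,
) -> list[MLRComponent]:
    comps = [
        MLRComponent(PROPORTIONAL_LABEL, slope=1.0),
        MLRComponent("class2_flat", slope=0.0),
        MLRComponent(
            "class3a_sub",
            slope=0.5,
            fix_slope=False,
            slope_bounds=(slope_margin, 1.0 - slope_margin),
        ),
        MLRComponent(
            "class3b_super",
            slope=1.5,
            fix_slope=False,
            slope_bounds=(1.0 + slope_margin, 10.0),
        ),
    ]
    if outlier:
        comps.append(
            MLRComponent(
                OUTLIER_LABEL,
                slope=1.0,
                intercept=0.0,
                fix_intercept=False,
                fix_slope=False,
                var_inflation=outlier_var_inflation,
            )
        )
    return comps


@dataclass
class DosagePoints:
    """Replicate-level (x, y) points grouped by gene."""

    x: np.ndarray
    y: np.ndarray
    gene_idx: np.ndarray
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("dosage points must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def build_dosage_points(
    rt: RatioTable,
    ann: GeneAnnotation,
    comparisons: Sequence[str] | None = None,
    genes: pd.Index | None = None,
    min_points: int = 2,
) -> DosagePoints:
    """Assemble panel points: x = per-gene mean log2 DNA ratio of the
    strain comparison (DNA replicates pooled), y = each replicate log2
    mRNA ratio.  Defaults to amplified genes of the panel strains; genes
    with fewer than ``min_points`` complete points are dropped."""
    if comparisons is None:
        comparisons = rt.comparison_ids
    if genes is None:
        sets = [
            pd.Index(ann.amplified_genes(rt.test_strain(c))) for c in comparisons
        ]
        genes = sets[0]
        for s in sets[1:]:
            genes = genes.union(s)
    frames = []
    for c in comparisons:
        dna = rt.dna(c)
        mrna = rt.mrna(c)
        common = genes.intersection(dna.index).intersection(mrna.index)
        sub = mrna.loc[common]
        sub.index.name = "gene_id"
        sub = sub.stack().rename("y").reset_index()
        sub["x"] = dna.reindex(sub["gene_id"]).to_numpy()
        frames.append(sub[["gene_id", "x", "y"]].dropna())
    pts = pd.concat(frames, ignore_index=True)
    counts = pts.groupby("gene_id").size()
    keep = counts.index[counts >= min_points]
    pts = pts[pts["gene_id"].isin(set(keep))]
    gene_ids = pd.Index(sorted(pts["gene_id"].unique()), name="gene_id")
    idx = gene_ids.get_indexer(pts["gene_id"])
    return DosagePoints(
        pts["x"].to_numpy(float), pts["y"].to_numpy(float), idx, gene_ids
    )


def _suff_stats(dp: DosagePoints) -> dict[str, np.ndarray]:
    G = dp.n_genes
    w = dict(
        n=np.bincount(dp.gene_idx, minlength=G).astype(float),
        sx=np.bincount(dp.gene_idx, weights=dp.x, minlength=G),
        sy=np.bincount(dp.gene_idx, weights=dp.y, minlength=G),
        sxx=np.bincount(dp.gene_idx, weights=dp.x * dp.x, minlength=G),
        sxy=np.bincount(dp.gene_idx, weights=dp.x * dp.y, minlength=G),
        syy=np.bincount(dp.gene_idx, weights=dp.y * dp.y, minlength=G),
    )
    return w


def _rss_matrix(stats_: Mapping[str, np.ndarray], a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene residual sum of squares under each line y = a_k + b_k x."""
    n, sx, sy = stats_["n"], stats_["sx"], stats_["sy"]
    sxx, sxy, syy = stats_["sxx"], stats_["sxy"], stats_["syy"]
    return (
        syy[:, None]
        - 2 * a[None, :] * sy[:, None]
        - 2 * b[None, :] * sxy[:, None]
        + 2 * a[None, :] * b[None, :] * sx[:, None]
        + (a ** 2)[None, :] * n[:, None]
        + (b ** 2)[None, :] * sxx[:, None]
    )


class MixtureLinearRegression(BaseEstimator):
    """EM fit of the dosage-response mixture.

    Parameters
    ----------
    components : list of MLRComponent, or None for the default set
        (proportional, flat, sub, super, outlier).
    n_starts : EM restarts with jittered free-slope initializations; the
        best log-likelihood wins.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    random_state : seed for the restart jitter.

    Fitted attributes (trailing underscore): ``components_``,
    ``weights_`` (mixing proportions), ``sigma_``, ``posteriors_``
    (genes x components DataFrame), ``labels_``, ``loglik_trace_``,
    ``converged_``, ``gene_ids_``.
    """

    def __init__(
        self,
        components: Sequence[MLRComponent] | None = None,
        n_starts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-6,
        outlier: bool = True,
        outlier_var_inflation: float = 5.0,
        slope_margin: float = 0.01,
        random_state: int | None = None,
    ):
        self.components = components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.outlier = outlier
        self.outlier_var_inflation = outlier_var_inflation
        self.slope_margin = slope_margin
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _component_set(self) -> list[MLRComponent]:
        if self.components is not None:
            if len(self.components) < 2:
                raise ValueError("need at least 2 mixture components")
            return [replace(c) for c in self.components]
        return default_components(
            self.slope_margin, self.outlier, self.outlier_var_inflation
        )

    @staticmethod
    def _loglik_matrix(stats_, a, b, sigma2, vinfl, pi):
        rss = _rss_matrix(stats_, a, b)
        var = sigma2 * vinfl[None, :]
        n = stats_["n"][:, None]
        ll = -0.5 * n * np.log(2 * np.pi * var) - rss / (2 * var)
        with np.errstate(divide="ignore"):
            return ll + np.log(pi)[None, :]

    def _em(self, dp: DosagePoints, comps, init_slopes, rng) -> dict:
        stats_ = _suff_stats(dp)
        K = len(comps)
        a = np.array([c.intercept for c in comps], float)
        b = np.array(init_slopes, float)
        vinfl = np.array([c.var_inflation for c in comps], float)
        fix_b = np.array([c.fix_slope for c in comps])
        fix_a = np.array([c.fix_intercept for c in comps])
        bounds = [c.slope_bounds for c in comps]
        pi = np.full(K, 1.0 / K)
        resid0 = dp.y - dp.x
        sigma2 = max(float(np.var(resid0)), 1e-4)
        frozen = np.zeros(K, bool)

        trace = []
        prev_ll = -np.inf
        converged = False
        post = None
        for _ in range(self.max_iter):
            logp = self._loglik_matrix(stats_, a, b, sigma2, vinfl, pi)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            post = np.exp(logp - norm[:, None])
            # M-step
            pi_new = post.mean(axis=0)
            newly = (pi_new < 1e-10) & ~frozen
            if newly.any():
                for k in np.where(newly)[0]:
                    logger.warning(
                        "component %s emptied (pi -> 0); frozen", comps[k].label
                    )
                frozen |= newly
            pi = np.where(frozen, 0.0, pi_new)
            s = pi.sum()
            if s <= 0:
                raise RuntimeError("all mixture components emptied")
            pi = pi / s
            for k in range(K):
                if frozen[k]:
                    continue
                w = post[:, k]
                if not fix_a[k] and not fix_b[k]:
                    # weighted OLS with intercept
                    A = np.array(
                        [
                            [np.dot(w, stats_["n"]), np.dot(w, stats_["sx"])],
                            [np.dot(w, stats_["sx"]), np.dot(w, stats_["sxx"])],
                        ]
                    )
                    rhs = np.array(
                        [np.dot(w, stats_["sy"]), np.dot(w, stats_["sxy"])]
                    )
                    det = np.linalg.det(A)
                    if abs(det) > 1e-12:
                        sol = np.linalg.solve(A, rhs)
                        a[k], b[k] = sol[0], sol[1]
                elif not fix_b[k]:
                    den = np.dot(w, stats_["sxx"])
                    if den > 1e-12:
                        b[k] = np.dot(w, stats_["sxy"]) / den
                b[k] = float(np.clip(b[k], bounds[k][0], bounds[k][1]))
            rss = _rss_matrix(stats_, a, b)
            num = float(np.sum(post * rss / vinfl[None, :]))
            den = float(np.sum(post * stats_["n"][:, None]))
            sigma2 = max(num / den, 1e-12)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= self.tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
        # final E-step at converged parameters
        logp = self._loglik_matrix(stats_, a, b, sigma2, vinfl, pi)
        norm = logsumexp(logp, axis=1)
        trace.append(float(norm.sum()))
        post = np.exp(logp - norm[:, None])
        return dict(
            a=a, b=b, pi=pi, sigma2=sigma2, post=post,
            trace=np.asarray(trace), converged=converged,
        )

    # -- public API --------------------------------------------------------

    def fit(self, X, y=None, groups=None) -> "MixtureLinearRegression":
        """Fit the mixture.

        ``X`` may be a DosagePoints object, or an array of x values with
        ``y`` the responses and ``groups`` the per-point gene labels.
        """
        if isinstance(X, DosagePoints):
            dp = X
        else:
            x = np.asarray(X, float).ravel()
            y = np.asarray(y, float).ravel()
            if groups is None:
                raise ValueError("groups (per-point gene ids) are required")
            gene_ids, gene_idx = np.unique(np.asarray(groups), return_inverse=True)
            dp = DosagePoints(x, y, gene_idx, pd.Index(gene_ids, name="gene_id"))
        counts = np.bincount(dp.gene_idx, minlength=dp.n_genes)
        if (counts < 2).any():
            raise ValueError("every gene needs >= 2 points")

        comps = self._component_set()
        rng = check_random_state(self.random_state)
        base_slopes = np.array([c.slope for c in comps], float)
        free = np.array([not c.fix_slope for c in comps])
        best = None
        for start in range(self.n_starts):
            init = base_slopes.copy()
            if start > 0:
                init[free] += rng.normal(0.0, 0.15, size=free.sum())
                for k, c in enumerate(comps):
                    init[k] = float(np.clip(init[k], *c.slope_bounds))
            res = self._em(dp, comps, init, rng)
            if best is None or res["trace"][-1] > best["trace"][-1]:
                best = res
        if not best["converged"]:
            logger.warning("EM did not converge in %d iterations", self.max_iter)

        labels = [c.label for c in comps]
        self.components_ = [
            replace(c, intercept=float(best["a"][k]), slope=float(best["b"][k]))
            for k, c in enumerate(comps)
        ]
        self.weights_ = pd.Series(best["pi"], index=labels, name="pi")
        self.sigma_ = float(np.sqrt(best["sigma2"]))
        self.posteriors_ = pd.DataFrame(
            best["post"], index=dp.gene_ids, columns=labels
        )
        self.labels_ = classify(self.posteriors_)
        self.loglik_trace_ = best["trace"]
        self.loglik_ = float(best["trace"][-1])
        self.converged_ = bool(best["converged"])
        self.gene_ids_ = dp.gene_ids
        self.dosage_points_ = dp
        return self

    def predict(self, X=None, y=None, groups=None) -> pd.Series:
        """Class labels: fitted genes by default, or new point sets
        scored under the fitted parameters."""
        if X is None:
            return self.labels_
        return classify(self.predict_proba(X, y, groups))

    def predict_proba(self, X, y=None, groups=None) -> pd.DataFrame:
        if isinstance(X, DosagePoints):
            dp = X
        else:
            x = np.asarray(X, float).ravel()
            y = np.asarray(y, float).ravel()
            gene_ids, gene_idx = np.unique(np.asarray(groups), return_inverse=True)
            dp = DosagePoints(x, y, gene_idx, pd.Index(gene_ids, name="gene_id"))
        stats_ = _suff_stats(dp)
        a = np.array([c.intercept for c in self.components_])
        b = np.array([c.slope for c in self.components_])
        vinfl = np.array([c.var_inflation for c in self.components_])
        logp = self._loglik_matrix(
            stats_, a, b, self.sigma_ ** 2, vinfl, self.weights_.to_numpy()
        )
        post = np.exp(logp - logsumexp(logp, axis=1)[:, None])
        return pd.DataFrame(
            post, index=dp.gene_ids, columns=[c.label for c in self.components_]
        )

    def conditional_fdr(self, class_label: str) -> float:
        return conditional_fdr(self, class_label)


def classify(posteriors: pd.DataFrame) -> pd.Series:
    """Maximum-posterior class per gene; exact ties go to the
    lower-index component (logged)."""
    arr = posteriors.to_numpy()
    idx = arr.argmax(axis=1)
    ties = (arr == arr[np.arange(len(arr)), idx][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "%d gene(s) with tied posteriors assigned to the first "
            "listed component", int(ties.sum()),
        )
    return pd.Series(
        posteriors.columns.to_numpy()[idx], index=posteriors.index, name="class"
    )


def conditional_fdr(fit: MixtureLinearRegression, class_label: str) -> float:
    """Mean posterior probability of not belonging to ``class_label``
    among genes called to it."""
    called = fit.labels_.index[fit.labels_ == class_label]
    if len(called) == 0:
        logger.warning("no genes called to %s: conditional FDR undefined", class_label)
        return float("nan")
    return float(1.0 - fit.posteriors_.loc[called, class_label].mean())


# ---------------------------------------------------------------------------
# Per-gene likelihood-ratio check of proportionality
# ---------------------------------------------------------------------------

def lrt_proportionality(
    dp: DosagePoints,
    method: str = "exact_f",
    rss_floor: float = 1e-12,
) -> pd.DataFrame:
    """Per-gene test of the null (intercept 0, slope 1) against free OLS.

    Lambda = n * ln(RSS0 / RSS1) with a variance floor on both residual
    sums; Lambda is 0 (p = 1) when both sit at the floor.  ``exact_f``
    maps the statistic monotonically to its exact F(2, n-2) reference
    under normal errors (calibrated at small n); ``chi2`` uses the
    asymptotic chi-squared on 2 df.  Genes with < 3 points or a single
    distinct x value are skipped with a warning.
    """
    if method not in ("exact_f", "chi2"):
        raise ValueError("method must be 'exact_f' or 'chi2'")
    s = _suff_stats(dp)
    n = s["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = s["sxx"] - s["sx"] ** 2 / n
        sxy_c = s["sxy"] - s["sx"] * s["sy"] / n
        syy_c = s["syy"] - s["sy"] ** 2 / n
    ok = (n >= 3) & (sxx_c > 1e-12)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning(
            "%d gene(s) skipped in LRT (need >=3 points and >=2 distinct x)",
            skipped,
        )
    slope = np.where(ok, sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), np.nan)
    rss1 = syy_c - slope * sxy_c
    rss0 = s["syy"] - 2 * s["sxy"] + s["sxx"]
    rss1f = np.maximum(rss1, rss_floor)
    rss0f = np.maximum(rss0, rss_floor)
    lam = n * np.log(rss0f / rss1f)
    both_floor = (rss0 <= rss_floor) & (rss1 <= rss_floor)
    lam = np.where(both_floor, 0.0, lam)
    if method == "chi2":
        p = stats.chi2.sf(lam, 2)
    else:
        fstat = ((rss0f - rss1f) / 2.0) / (rss1f / np.maximum(n - 2, 1))
        p = stats.f.sf(fstat, 2, np.maximum(n - 2, 1))
    p = np.where(both_floor, 1.0, p)
    out = pd.DataFrame(
        {"n": n.astype(int), "lambda": lam, "pvalue": p}, index=dp.gene_ids
    )
    return out[ok]


@dataclass
class Pi0Result:
    pi0: float
    pi0_by_lambda: pd.Series
    qvalues: pd.Series


def estimate_pi0(
    pvalues: pd.Series | np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    method: str = "plugin",
    plugin_lambda: float = 0.5,
) -> Pi0Result:
    """Null-proportion estimate pi0 and q-values from a p-value vector.

    pi0(l) = #{p > l} / (m (1-l)); the default is the plug-in estimator
    at l = 0.5, ``method='smoother'`` fits a cubic spline over the grid
    and reads it off at the largest l.  q-values are the pi0-scaled
    step-up transform.
    """
    p = pd.Series(pvalues).astype(float)
    if p.empty:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lambda_grid = np.asarray(sorted(lambda_grid))
    m = len(p)
    by_lambda = pd.Series(
        [(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid],
        index=lambda_grid,
    )
    if method == "plugin":
        pi0 = float((p > plugin_lambda).sum() / (m * (1 - plugin_lambda)))
    elif method == "smoother":
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(lambda_grid, by_lambda.to_numpy(), k=3)
        pi0 = float(spl(lambda_grid[-1]))
    else:
        raise ValueError("method must be 'plugin' or 'smoother'")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    order = np.argsort(p.to_numpy(), kind="mergesort")
    ranked = p.to_numpy()[order]
    q_sorted = pi0 * ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return Pi0Result(pi0, by_lambda, pd.Series(q, index=p.index, name="qvalue"))


@dataclass
class NullProportionReport:
    """Agreement between the mixture's non-proportional share and the
    LRT-based non-null share, both computed among genes with a linear
    mRNA:DNA relationship (the outlier class is excluded).  Note the two
    conventions: ``mlr_nonproportional`` counts genes classified away
    from the proportional component; ``lrt_nonnull`` is 1 - pi0, the
    estimated share of genes violating (intercept 0, slope 1)."""

    mlr_nonproportional: float
    mlr_proportional: float
    lrt_nonnull: float
    pi0: float
    difference: float
    n_genes: int


def compare_null_proportions(
    fit: MixtureLinearRegression,
    lrt: pd.DataFrame,
    pi0_method: str = "plugin",
) -> NullProportionReport:
    """Compare mixture and LRT null-share estimates on the same genes."""
    if not set(lrt.index).issubset(set(fit.labels_.index)):
        raise ValueError("MLR and LRT gene sets do not match")
    linear = fit.labels_.index[fit.labels_ != OUTLIER_LABEL]
    common = linear.intersection(lrt.index)
    if len(common) == 0:
        raise ValueError("no genes in common between MLR and LRT results")
    labels = fit.labels_.loc[common]
    mlr_prop = float((labels == PROPORTIONAL_LABEL).mean())
    res = estimate_pi0(lrt.loc[common, "pvalue"], method=pi0_method)
    report = NullProportionReport(
        mlr_nonproportional=1.0 - mlr_prop,
        mlr_proportional=mlr_prop,
        lrt_nonnull=1.0 - res.pi0,
        pi0=res.pi0,
        difference=abs((1.0 - mlr_prop) - (1.0 - res.pi0)),
        n_genes=len(common),
    )
    return report
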