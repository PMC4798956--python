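"""Seed-reproducible synthetic datasets with known dosage-response classes.

The generator emulates the two study designs used to probe dosage
compensation in aneuploid yeast:

* a *pair* design — one naturally aneuploid strain against its isogenic
  euploid control, duplicate RNA-seq and single DNA-seq per strain;
* a *panel* design — isogenic strains carrying 2, 3 or 4 copies of one
  chromosome (linear copy ratios 1 / 1.5 / 2 against the euploid),
  triplicate RNA-seq and duplicate DNA-seq per strain.

Each amplified gene carries a ground-truth dosage-response class: mRNA
abundance rises proportionally with copy number (slope 1 on the log2
DNA-ratio scale), sub-proportionally (slope in (0,1)), not at all
(compensated, slope 0) or super-proportionally (slope > 1).  Counts are
negative-binomial (NB1: variance mu*(1+phi)); biological replicates add
log-normal multiplicative jitter sized so the per-gene SD of replicate
log2 mRNA ratios lands at ``replicate_sd`` (defaults reproduce the
0.12-0.3 range seen in replicate sequencing of such strains).
Trans-acting "indirect response" modules shift whole functional
categories, mimicking expression programs triggered by the aneuploid
state rather than by gene dosage itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_normalize import (
    CategoryMap,
    CountMatrix,
    GeneAnnotation,
    SampleMeta,
    samples_frame,
)

CLASS_LABELS = (
    "proportional",
    "sub_proportional",
    "compensated_flat",
    "super_proportional",
)

DEFAULT_CLASS_FRACTIONS = {
    "proportional": 0.75,
    "sub_proportional": 0.10,
    "compensated_flat": 0.10,
    "super_proportional": 0.05,
}


@dataclass(frozen=True)
class TransModule:
    """A trans-acting response module: every member gene shifts by
    ``effect_log2`` in aneuploid samples regardless of its own copy
    number.  ``n_amplified`` members are drawn from amplified genes (to
    model indirect responses overlapping the amplified chromosome); the
    rest from unamplified genes."""

    category: str
    effect_log2: float
    n_genes: int
    n_amplified: int = 0


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_chromosomes: int = 8
    amplified_chromosome: str = "chr01"
    amplified_fraction: float = 0.25
    copy_ratio_linear: float = 2.0
    panel_copy_states: tuple[float, ...] = (1.0, 1.5, 2.0)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    sub_slope: float = 0.4
    super_slope: float = 1.5
    replicate_sd: float = 0.2
    dosage_sd: float = 0.18
    dna_measurement_sd: float = 0.05
    n_rna_reps: int = 2
    n_dna_reps: int = 1
    n_strain_pairs: int = 1
    trans_modules: tuple[TransModule, ...] = ()
    telomere_unamplified_fraction: float = 0.0
    nb_dispersion: float = 0.05
    mean_rna_depth: float = 1000.0
    mean_dna_depth: float = 1000.0
    background_categories: int = 10
    background_category_size: int = 40
    spike_rate: float = 0.1
    mean_cells: float = 1e7
    seed: int = 0

    def validate(self) -> None:
        self.trans_modules = tuple(
            TransModule(**m) if isinstance(m, dict) else m
            for m in self.trans_modules
        )
        tot = sum(self.class_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {tot}")
        unknown = set(self.class_fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class label(s): {sorted(unknown)}")
        if min(self.replicate_sd, self.dosage_sd, self.dna_measurement_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_strain_pairs < 1:
            raise ValueError("n_strain_pairs must be >= 1")
        if self.copy_ratio_linear <= 0 or any(
            c <= 0 for c in self.panel_copy_states
        ):
            raise ValueError("copy ratios must be > 0")
        if not 0 <= self.telomere_unamplified_fraction < 1:
            raise ValueError("telomere_unamplified_fraction must be in [0,1)")
        if not 0 < self.amplified_fraction <= 1:
            raise ValueError("amplified_fraction must be in (0,1]")


def default_pair_config(**overrides) -> SimConfig:
    """Pair design: duplicate RNA, single DNA per strain."""
    return replace(SimConfig(), **overrides)


def default_panel_config(**overrides) -> SimConfig:
    """Panel design: triplicate RNA, duplicate DNA per strain."""
    base = SimConfig(n_rna_reps=3, n_dna_reps=2)
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Per-gene truth: class label, true slope, module membership and
    per-strain linear copy number."""

    genes: pd.DataFrame        # index gene_id: class_label, true_slope, module, amplified, telomeric
    copy_numbers: pd.DataFrame  # genes x strains, linear copy ratio vs euploid

    @property
    def class_labels(self) -> pd.Series:
        return self.genes["class_label"]

    def genes_in_class(self, label: str) -> pd.Index:
        return self.genes.index[self.genes["class_label"] == label]


def _nb1_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB1 counts: variance mu*(1+phi), gamma-Poisson mixture."""
    mu = np.clip(mu, 1e-12, None)
    if phi <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=mu / phi, scale=phi)
    return rng.poisson(lam)


def _layout_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    width = len(str(n))
    gene_ids = [f"g{i+1:0{width}d}" for i in range(n)]
    n_amp_chr = int(round(n * cfg.amplified_fraction))
    others = [
        f"chr{c+2:02d}" for c in range(max(cfg.n_chromosomes - 1, 1))
    ]
    chroms = [cfg.amplified_chromosome] * n_amp_chr + [
        others[i % len(others)] for i in range(n - n_amp_chr)
    ]
    lengths = rng.integers(500, 4000, size=n)
    # telomere-proximal genes on the amplified chromosome escape amplification
    telomeric = np.zeros(n, dtype=bool)
    n_telo = int(round(n_amp_chr * cfg.telomere_unamplified_fraction))
    if n_telo:
        telomeric[:n_telo] = True  # leading block = chromosome end
    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "length_bp": lengths,
            "telomeric": telomeric,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    df["amplified"] = (df["chromosome"] == cfg.amplified_chromosome) & ~df["telomeric"]
    return df


def _assign_classes(
    cfg: SimConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    amp = layout.index[layout["amplified"]]
    labels = pd.Series("unamplified", index=layout.index, name="class_label")
    fracs = [cfg.class_fractions.get(c, 0.0) for c in CLASS_LABELS]
    counts = np.floor(np.asarray(fracs) * len(amp)).astype(int)
    rem = len(amp) - counts.sum()
    order = np.argsort(-(np.asarray(fracs) * len(amp) - counts))
    for i in range(rem):
        counts[order[i % len(order)]] += 1
    perm = rng.permutation(len(amp))
    pos = 0
    for label, k in zip(CLASS_LABELS, counts):
        labels.iloc[layout.index.get_indexer(amp[perm[pos:pos + k]])] = label
        pos += k
    slopes = labels.map(
        {
            "proportional": 1.0,
            "sub_proportional": cfg.sub_slope,
            "compensated_flat": 0.0,
            "super_proportional": cfg.super_slope,
            "unamplified": 0.0,
        }
    )
    out = layout.copy()
    out["class_label"] = labels
    out["true_slope"] = slopes.astype(float)
    return out


def _assign_modules(
    cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.Series, dict[str, float]]:
    module = pd.Series("", index=truth.index, name="module")
    effects: dict[str, float] = {}
    unamp_pool = list(truth.index[~truth["amplified"]])
    amp_pool = list(truth.index[truth["amplified"]])
    rng.shuffle(unamp_pool)
    rng.shuffle(amp_pool)
    for mod in cfg.trans_modules:
        n_unamp = mod.n_genes - mod.n_amplified
        if n_unamp > len(unamp_pool) or mod.n_amplified > len(amp_pool):
            raise ValueError(f"module {mod.category!r} larger than gene pool")
        members = [unamp_pool.pop() for _ in range(n_unamp)]
        members += [amp_pool.pop() for _ in range(mod.n_amplified)]
        module.loc[members] = mod.category
        effects[mod.category] = mod.effect_log2
    return module, effects


def _background_categories(
    cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """Random functional categories (no expression effect) so enrichment
    has a realistic universe; returns per-gene frozenset of categories."""
    cats: dict[str, list[str]] = {}
    genes = list(truth.index)
    for i in range(cfg.background_categories):
        name = f"bgcat{i+1:02d}"
        size = min(cfg.background_category_size, len(genes))
        cats[name] = list(rng.choice(genes, size=size, replace=False))
    per_gene: dict[str, set[str]] = {g: set() for g in genes}
    for name, members in cats.items():
        for g in members:
            per_gene[g].add(name)
    mod = truth["module"]
    for g, m in mod.items():
        if m:
            per_gene[g].add(m)
    return pd.Series({g: frozenset(s) for g, s in per_gene.items()})


def _simulate_counts(
    cfg: SimConfig,
    truth: pd.DataFrame,
    module_effects: dict[str, float],
    strains: dict[str, float],
    rng: np.random.Generator,
    rep_multiplier: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts for a set of strains given per-strain nominal copy ratio.

    The true per-gene dosage of an amplified gene deviates from the
    chromosome's nominal copy ratio by a log2 deviation of SD
    ``dosage_sd`` (segmental variation, partial amplification); this
    deviation is *biological* — it drives both the DNA reads and, through
    the gene's response slope, the mRNA.  DNA samples add a smaller
    per-sample measurement jitter (``dna_measurement_sd``), so observed
    DNA log2 ratios on the amplified chromosome spread with SD
    sqrt(dosage_sd^2 + 2*dna_measurement_sd^2).  Returns
    (counts, samples, copy_numbers) with true linear dosages."""
    n = len(truth)
    len_kb = truth["length_bp"].to_numpy() / 1000.0
    base = rng.lognormal(mean=0.0, sigma=0.8, size=n)
    base_rate = base * len_kb
    rna_scale = cfg.mean_rna_depth / base_rate.mean()
    dna_scale = cfg.mean_dna_depth / len_kb.mean()

    slopes = truth["true_slope"].to_numpy()
    amplified = truth["amplified"].to_numpy()
    module = truth["module"]

    copy_numbers = pd.DataFrame(1.0, index=truth.index, columns=list(strains))
    metas: list[SampleMeta] = []
    cols: dict[str, np.ndarray] = {}
    # per-sample log jitter: replicate_sd targets the SD of the log2
    # ratio of two independent samples -> each contributes sd/sqrt(2)
    rna_jit = cfg.replicate_sd / np.sqrt(2.0) * np.log(2.0)
    dna_jit = cfg.dna_measurement_sd * np.log(2.0)

    for strain, copy_ratio in strains.items():
        if copy_ratio != 1.0:
            delta = np.where(
                amplified, rng.normal(0.0, cfg.dosage_sd, size=n), 0.0
            )
            dose = np.where(amplified, copy_ratio * 2.0 ** delta, 1.0)
        else:
            dose = np.ones(n)
        copy_numbers[strain] = dose
        # trans responses are triggered by the aneuploid state itself,
        # so a copy-1 isogenic control shows none
        trans = np.ones(n)
        if copy_ratio != 1.0:
            for cat, eff in module_effects.items():
                trans[np.asarray(module == cat)] *= 2.0 ** eff
        rna_dose = dose ** slopes
        mult = 1 if rep_multiplier is None else rep_multiplier.get(strain, 1)
        for rep in range(1, mult * cfg.n_rna_reps + 1):
            mu = rna_scale * base_rate * rna_dose * trans
            mu = mu * np.exp(rng.normal(0.0, rna_jit, size=n))
            name = f"{strain}_RNA_r{rep}"
            cols[name] = _nb1_counts(rng, mu, cfg.nb_dispersion)
            cells = cfg.mean_cells * rng.uniform(0.8, 1.2)
            metas.append(
                SampleMeta(
                    name,
                    strain,
                    "RNA",
                    rep,
                    ploidy_label=f"{copy_ratio:g}x",
                    spike_total=float(np.round(cfg.spike_rate * cells)),
                    cells_counted=float(np.round(cells)),
                )
            )
        for rep in range(1, mult * cfg.n_dna_reps + 1):
            mu = dna_scale * len_kb * dose
            if dna_jit > 0:
                mu = mu * np.exp(rng.normal(0.0, dna_jit, size=n))
            name = f"{strain}_DNA_r{rep}"
            cols[name] = _nb1_counts(rng, mu, cfg.nb_dispersion)
            cells = cfg.mean_cells * rng.uniform(0.8, 1.2)
            metas.append(
                SampleMeta(
                    name,
                    strain,
                    "DNA",
                    rep,
                    ploidy_label=f"{copy_ratio:g}x",
                    spike_total=float(np.round(cfg.spike_rate * cells)),
                    cells_counted=float(np.round(cells)),
                )
            )
    counts = pd.DataFrame(cols, index=truth.index)
    return counts, samples_frame(metas), copy_numbers


def _finalize(
    cfg: SimConfig,
    truth: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    categories: pd.Series,
    aneuploid_strains: Sequence[str],
) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    amplified_in = truth["amplified"].map(
        lambda a: frozenset(aneuploid_strains) if a else frozenset()
    )
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": truth["chromosome"],
                "length_bp": truth["length_bp"],
                "amplified_in": amplified_in,
                "categories": categories,
            }
        )
    )
    gt = GroundTruth(
        truth[["class_label", "true_slope", "module", "amplified", "telomeric"]].copy(),
        copy_numbers,
    )
    return CountMatrix(counts, samples), ann, gt


def simulate_pair(cfg: SimConfig) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    """Aneuploid/euploid strain pairs with shared ground truth.

    With ``n_strain_pairs=1`` the strains are 'aneu' and 'eu'.  With more
    pairs ('aneu1'/'eu1', 'aneu2'/'eu2', ...) the gene classes are the
    same in every pair but all measurements are independent — the setup
    behind the four-replicate intersection rule, where a gene must fall
    below threshold in every replicate of two independent strain pairs.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    layout = _layout_genes(cfg, rng)
    truth = _assign_classes(cfg, layout, rng)
    truth["module"], effects = _assign_modules(cfg, truth, rng)
    categories = _background_categories(cfg, truth, rng)
    if cfg.n_strain_pairs == 1:
        strains = {"eu": 1.0, "aneu": cfg.copy_ratio_linear}
        aneuploid = ["aneu"]
    else:
        strains = {}
        aneuploid = []
        for i in range(1, cfg.n_strain_pairs + 1):
            strains[f"eu{i}"] = 1.0
            strains[f"aneu{i}"] = cfg.copy_ratio_linear
            aneuploid.append(f"aneu{i}")
    counts, samples, copies = _simulate_counts(cfg, truth, effects, strains, rng)
    return _finalize(cfg, truth, counts, samples, copies, categories, aneuploid)


def pair_comparisons(cm: CountMatrix) -> list[tuple[str, str, str]]:
    """(test, ref, comparison_id) sample pairs matching each 'aneu*'
    strain with its own 'eu*' euploid, replicates matched by number."""
    strains = set(cm.samples["strain"])
    pairs = []
    for s in sorted(strains):
        if not s.startswith("aneu"):
            continue
        ref = "eu" + s[len("aneu"):]
        if ref not in strains:
            raise ValueError(f"no euploid partner {ref!r} for strain {s!r}")
        comp = f"{s}_vs_{ref}"
        for mol in ("RNA", "DNA"):
            for t, r in zip(cm.samples_for(s, mol), cm.samples_for(ref, mol)):
                pairs.append((t, r, comp))
    return pairs


def simulate_panel(cfg: SimConfig) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    """Isogenic panel: one strain per copy state in ``panel_copy_states``
    plus the euploid reference ('eu')."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    layout = _layout_genes(cfg, rng)
    truth = _assign_classes(cfg, layout, rng)
    truth["module"], effects = _assign_modules(cfg, truth, rng)
    categories = _background_categories(cfg, truth, rng)
    strains = {"eu": 1.0}
    panel_names = []
    for state in cfg.panel_copy_states:
        name = f"cn{int(round(state * 10)):02d}"
        strains[name] = state
        panel_names.append(name)
    # every panel comparison gets its own paired euploid control cultures
    counts, samples, copies = _simulate_counts(
        cfg, truth, effects, strains, rng,
        rep_multiplier={"eu": len(cfg.panel_copy_states)},
    )
    amplified_strains = [
        n for n, s in strains.items() if n != "eu" and s != 1.0
    ]
    cm, ann, gt = _finalize(
        cfg, truth, counts, samples, copies, categories, amplified_strains
    )
    gt.genes.attrs["panel_strains"] = panel_names
    return cm, ann, gt


def panel_pairs(cm: CountMatrix, ref_strain: str = "eu") -> list[tuple[str, str, str]]:
    """(test, ref, comparison_id) sample pairs for every non-reference
    strain against the euploid.

    When the euploid carries enough replicates, each comparison is
    allocated its own disjoint block of euploid samples (paired control
    cultures); otherwise the same euploid replicates are reused across
    comparisons.
    """
    pairs = []
    strains = [s for s in cm.samples["strain"].unique() if s != ref_strain]
    for k, strain in enumerate(strains):
        comp = f"{strain}_vs_{ref_strain}"
        for mol in ("RNA", "DNA"):
            tests = cm.samples_for(strain, mol)
            refs_all = cm.samples_for(ref_strain, mol)
            n = len(tests)
            if len(refs_all) >= (k + 1) * n:
                refs = refs_all[k * n:(k + 1) * n]
            else:
                refs = refs_all
            for t, r in zip(tests, refs):
                pairs.append((t, r, comp))
    return pairs


DEFAULT_CNV_RATE_MAP = {
    "compensated_flat": 0.05,
    "sub_proportional": 0.04,
    "super_proportional": 0.02,
    "proportional": 0.01,
    "unamplified": 0.01,
}

DEFAULT_VGVM_MAP = {
    "compensated_flat": 0.5,
    "sub_proportional": 0.7,
    "super_proportional": 1.2,
    "proportional": 1.5,
    "unamplified": 1.2,
}


def simulate_population_cnv(
    classes: pd.Series,
    n_strains: int = 103,
    rate_map: Mapping[str, float] | None = None,
    vgvm_map: Mapping[str, float] | None = None,
    vgvm_sigma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Population CNV survey: per-gene number of strains (out of
    ``n_strains``) carrying a duplication, binomial with a class-dependent
    per-strain rate, plus a log-normal expression-constraint value Vg/Vm
    around a class-dependent median.

    ``classes`` is a gene-indexed Series of class labels (ground-truth
    labels or analysis groups).  Returns a DataFrame with columns
    n_strains_amplified and vg_vm; the population size is kept in
    ``attrs['n_strains']``.
    """
    rate_map = dict(DEFAULT_CNV_RATE_MAP if rate_map is None else rate_map)
    vgvm_map = dict(DEFAULT_VGVM_MAP if vgvm_map is None else vgvm_map)
    rates = classes.map(rate_map)
    if rates.isna().any():
        missing = sorted(classes[rates.isna()].unique())
        raise ValueError(f"no CNV rate for class(es) {missing}")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("CNV rates must lie in [0,1]")
    medians = classes.map(vgvm_map)
    if (medians <= 0).any():
        raise ValueError("Vg/Vm medians must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_amp = rng.binomial(n_strains, rates.to_numpy())
    vgvm = medians.to_numpy() * rng.lognormal(0.0, vgvm_sigma, size=len(classes))
    out = pd.DataFrame(
        {"n_strains_amplified": n_amp, "vg_vm": vgvm},
        index=classes.index,
    )
    out.attrs["n_strains"] = n_strains
    return out
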