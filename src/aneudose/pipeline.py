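"""End-to-end orchestration: data (simulated or read) -> normalization ->
log2 ratio tables -> threshold calls with permutation FDR -> optional
mixture-model and LRT stage on panels -> indirect-response filter ->
effect-size tertiles -> population CNV / buffering report, with a
provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evolution_scores import evolution_report
from .io_normalize import (
    CategoryMap,
    CountMatrix,
    GeneAnnotation,
    RatioTable,
    log2_ratios,
    read_counts,
    read_gmt,
    rpkm_normalize,
    spike_in_normalize,
    write_annotation,
    write_counts,
    write_gmt,
    write_ratio_table,
)
from .mlr_model import (
    MixtureLinearRegression,
    build_dosage_points,
    compare_null_proportions,
    conditional_fdr,
    estimate_pi0,
    lrt_proportionality,
)
from .response_filter import (
    filter_amplified_calls,
    partition_by_effect,
    strain_enrichment,
)
from .synthetic import (
    SimConfig,
    TransModule,
    default_pair_config,
    default_panel_config,
    pair_comparisons,
    panel_pairs,
    simulate_pair,
    simulate_panel,
    simulate_population_cnv,
)
from .threshold_caller import (
    ThresholdSpec,
    call_lower_expressed,
    difference_matrix,
    permutation_fdr,
    write_calls,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None   # {"design": "pair"|"panel", **SimConfig overrides}
    inputs: dict | None = None     # paths: counts, samples, annotation, [categories], [cnv]
    normalization: str = "rpkm"    # rpkm | rpkm_excl_amplified | spike_in
    ref_strain: str | None = None
    k_sd: float = 1.0
    n_permutations: int = 10000
    de_fdr: float = 0.01
    enrich_p: float = 0.0004
    min_strains: int = 3
    run_mlr: bool | None = None    # default: on for panel simulations
    mlr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must set exactly one of 'simulate' and 'inputs'"
            )
        if self.normalization not in ("rpkm", "rpkm_excl_amplified", "spike_in"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    count_matrix: CountMatrix
    annotation: GeneAnnotation
    truth: Any
    ratio_table: RatioTable
    call_sets: dict
    pooled_calls: pd.DataFrame
    revised_calls: pd.DataFrame
    removed_calls: pd.DataFrame
    tertiles: pd.Series
    enrichment: dict
    cnv_records: pd.DataFrame | None
    evo_report: pd.DataFrame | None
    mlr_fit: MixtureLinearRegression | None
    lrt: pd.DataFrame | None
    null_proportion_report: Any
    manifest: dict


def _sim_config(spec: dict, seed: int) -> tuple[str, SimConfig]:
    spec = dict(spec)
    design = spec.pop("design", "pair")
    mods = spec.pop("trans_modules", None)
    if mods is not None:
        spec["trans_modules"] = tuple(
            TransModule(**m) if isinstance(m, dict) else m for m in mods
        )
    spec.setdefault("seed", seed)
    if design == "pair":
        return design, default_pair_config(**spec)
    if design == "panel":
        return design, default_panel_config(**spec)
    raise ValueError(f"unknown design {design!r}")


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 4)
    manifest: dict = {
        "package": "aneudose",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    hashed_cfg = {k: v for k, v in manifest["config"].items() if k != "outdir"}
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(hashed_cfg, sort_keys=True).encode()
    ).hexdigest()

    # ---- stage: data -----------------------------------------------------
    design = None
    truth = None
    try:
        if cfg.simulate is not None:
            design, sim_cfg = _sim_config(cfg.simulate, seeds[0])
            simulate = simulate_pair if design == "pair" else simulate_panel
            cm, ann, truth = simulate(sim_cfg)
            write_counts(cm, out / "counts.tsv", out / "samples.tsv")
            write_annotation(ann, out / "annotation.tsv")
            truth.genes.to_csv(out / "truth.tsv", sep="\t")
            write_gmt(ann.category_map(), out / "categories.gmt")
            cmap = ann.category_map()
        else:
            cm, ann = read_counts(
                cfg.inputs["counts"], cfg.inputs["samples"], cfg.inputs["annotation"]
            )
            cmap = (
                read_gmt(cfg.inputs["categories"])
                if "categories" in cfg.inputs
                else ann.category_map()
            )
        manifest["stages"]["data"] = {
            "n_genes": int(len(cm.gene_ids)),
            "n_samples": int(cm.counts.shape[1]),
        }
    except Exception as err:
        raise PipelineError(f"[data] {err}") from err

    # ---- stage: normalize + ratios --------------------------------------
    try:
        ref = cfg.ref_strain
        amped = set().union(*ann.table["amplified_in"])
        candidates = [
            s for s in cm.samples["strain"].unique() if s not in amped
        ]
        if ref is None:
            if not candidates:
                raise ValueError("no euploid reference strain found")
            ref = "eu" if "eu" in candidates else sorted(candidates)[0]
        if cfg.normalization == "spike_in":
            abund = spike_in_normalize(cm)
        elif cfg.normalization == "rpkm_excl_amplified":
            excl = sorted(
                {ann.table.loc[g, "chromosome"]
                 for g in ann.gene_ids
                 if ann.table.loc[g, "amplified_in"]}
            )
            abund = rpkm_normalize(cm, ann, exclude_chromosomes=excl)
        else:
            abund = rpkm_normalize(cm, ann)
        if design == "pair" and len(candidates) > 1:
            pairs = pair_comparisons(cm)   # aneu_i matched with eu_i
        elif cfg.ref_strain is None and len(candidates) > 1 and design is None:
            raise ValueError(
                "multiple euploid strains present: set ref_strain in the config"
            )
        else:
            pairs = panel_pairs(cm, ref_strain=ref)
        rt = log2_ratios(abund, cm.samples, pairs)
        write_ratio_table(rt, out / "ratios.tsv", out / "comparisons.tsv")
        manifest["stages"]["normalize"] = {
            "method": cfg.normalization,
            "ref_strain": ref,
            "n_dropped": int(len(rt.dropped)),
        }
    except Exception as err:
        raise PipelineError(f"[normalize] {err}") from err

    # ---- stage: threshold calls + permutation FDR -----------------------
    try:
        spec = ThresholdSpec(k_sd=cfg.k_sd)
        call_sets = {}
        pooled = []
        perm_rng = np.random.default_rng(seeds[1])
        # comparisons whose test strains amplify the same gene set are
        # intersected into one call rule (the four-replicate use); other
        # strains get their own call set
        groups: dict[frozenset, list[str]] = {}
        for c in rt.comparison_ids:
            amp = frozenset(ann.amplified_genes(rt.test_strain(c)))
            if not amp:
                continue
            groups.setdefault(amp, []).append(c)
        for comps in groups.values():
            label = "+".join(sorted({rt.test_strain(c) for c in comps}))
            cs = call_lower_expressed(rt, ann, spec, comps)
            if cfg.n_permutations and len(cs.called_genes):
                d = difference_matrix(rt, cs)
                perm = permutation_fdr(d, cfg.n_permutations, perm_rng)
                cs.fdr_estimate = perm.fdr
            call_sets[label] = cs
            write_calls(cs, out / f"calls_{label}.tsv")
            pooled.append(cs.calls[cs.calls["called"]])
            manifest["stages"][f"threshold_{label}"] = {
                "n_assessed": int(cs.n_assessed),
                "n_called": int(len(cs.called_genes)),
                "n_not_assessed": int(len(cs.not_assessed)),
                "fdr_estimate": None
                if cs.fdr_estimate is None
                else float(cs.fdr_estimate),
            }
        pooled_calls = (
            pd.concat(pooled) if pooled else pd.DataFrame(
                columns=["called", "n_replicates_below", "n_replicates",
                         "effect_size", "strain"]
            )
        )
        if pooled_calls.index.has_duplicates:
            # a gene amplified in several strains is pooled once, with its
            # strongest effect
            pooled_calls = pooled_calls.sort_values("effect_size")
            pooled_calls = pooled_calls[~pooled_calls.index.duplicated()]
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"[threshold] {err}") from err

    # ---- stage: MLR + LRT (panel designs) -------------------------------
    mlr_fit = None
    lrt = None
    np_report = None
    run_mlr = cfg.run_mlr if cfg.run_mlr is not None else design == "panel"
    if run_mlr:
        try:
            dp = build_dosage_points(rt, ann)
            mlr_fit = MixtureLinearRegression(
                random_state=seeds[2], **cfg.mlr
            ).fit(dp)
            mlr_fit.posteriors_.to_csv(out / "posteriors.tsv", sep="\t")
            mlr_fit.labels_.to_frame("class").to_csv(out / "classes.tsv", sep="\t")
            comp_rows = pd.DataFrame(
                {
                    "label": [c.label for c in mlr_fit.components_],
                    "intercept": [c.intercept for c in mlr_fit.components_],
                    "slope": [c.slope for c in mlr_fit.components_],
                    "pi": mlr_fit.weights_.to_numpy(),
                }
            )
            comp_rows.to_csv(out / "components.tsv", sep="\t", index=False)
            fdrs = {
                lab: conditional_fdr(mlr_fit, lab)
                for lab in mlr_fit.weights_.index
                if (mlr_fit.labels_ == lab).any()
            }
            pd.Series(fdrs, name="conditional_fdr").to_csv(
                out / "fdr.tsv", sep="\t", index_label="class"
            )
            lrt = lrt_proportionality(dp)
            pi0 = estimate_pi0(lrt["pvalue"])
            lrt_out = lrt.copy()
            lrt_out["qvalue"] = pi0.qvalues
            lrt_out.to_csv(out / "lrt.tsv", sep="\t", index_label="gene_id")
            (out / "pi0.txt").write_text(f"{pi0.pi0:.6f}\n")
            np_report = compare_null_proportions(mlr_fit, lrt)
            manifest["stages"]["mlr"] = {
                "pi": {k: float(v) for k, v in mlr_fit.weights_.items()},
                "sigma": mlr_fit.sigma_,
                "conditional_fdr": {k: float(v) for k, v in fdrs.items()},
                "pi0": pi0.pi0,
                "agreement_difference": np_report.difference,
            }
            # on panels the pooled call set comes from the mixture classes
            # (per-strain threshold call sets remain on disk for reference)
            sub_genes = mlr_fit.labels_.index[
                mlr_fit.labels_.isin(["class3a_sub", "class2_flat"])
            ]
            eff = []
            for c in rt.comparison_ids:
                eff.append(rt.mrna(c).mean(axis=1) - rt.dna(c))
            eff = pd.concat(eff, axis=1).mean(axis=1)
            strain_of = pd.Series(
                {
                    g: max(ann.table.loc[g, "amplified_in"], default="")
                    for g in sub_genes
                }
            )
            pooled_calls = pd.DataFrame(
                {
                    "called": True,
                    "n_replicates_below": np.nan,
                    "n_replicates": np.nan,
                    "effect_size": eff.reindex(sub_genes),
                    "strain": strain_of,
                },
                index=sub_genes,
            )
        except Exception as err:
            raise PipelineError(f"[mlr] {err}") from err

    # ---- stage: indirect-response filter --------------------------------
    try:
        strain_ref = {
            rt.test_strain(c): rt.comparisons.loc[c, "ref_strain"]
            for c in rt.comparison_ids
        }
        enrichment = {}
        per_strain: dict[str, pd.DataFrame] = {}
        for label in pooled_calls["strain"].unique():
            if not label:
                continue
            tabs = []
            for s in str(label).split("+"):
                if s not in per_strain:
                    per_strain[s] = strain_enrichment(
                        cm, ann, s, strain_ref.get(s, ref), cmap,
                        fdr_threshold=cfg.de_fdr,
                    )
                    per_strain[s].to_csv(out / f"enrichment_{s}.tsv", sep="\t")
                tabs.append(per_strain[s])
            # a category enriched in any member strain triggers removal
            enrichment[label] = pd.concat(tabs)
        revised, removed = filter_amplified_calls(
            pooled_calls, enrichment, cmap, p_threshold=cfg.enrich_p
        )
        tertiles = partition_by_effect(revised) if len(revised) else pd.Series(
            dtype=object, name="effect_tertile"
        )
        revised.assign(effect_tertile=tertiles).to_csv(
            out / "revised_calls.tsv", sep="\t", index_label="gene_id"
        )
        removed.to_csv(out / "removed_calls.tsv", sep="\t", index_label="gene_id")
        manifest["stages"]["filter"] = {
            "n_calls": int(len(pooled_calls)),
            "n_removed": int(len(removed)),
            "removal_fraction": float(revised.attrs.get("removal_fraction", 0.0)),
        }
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"[filter] {err}") from err

    # ---- stage: evolution ------------------------------------------------
    cnv_records = None
    evo = None
    try:
        if cfg.inputs is not None and "cnv" in cfg.inputs:
            cnv_records = pd.read_csv(
                cfg.inputs["cnv"], sep="\t", index_col="gene_id"
            )
        elif truth is not None:
            cnv_records = simulate_population_cnv(
                truth.class_labels, seed=seeds[3]
            )
            cnv_records.to_csv(out / "cnv.tsv", sep="\t", index_label="gene_id")
        if cnv_records is not None and len(revised):
            groups = tertiles.copy()
            assessed_amp = pd.Index(
                sorted(
                    set().union(
                        *(set(cs.calls.index) for cs in call_sets.values())
                    )
                )
            ) if call_sets else pd.Index([])
            prop = assessed_amp.difference(pooled_calls.index)
            groups = pd.concat(
                [groups, pd.Series("proportionate_amplified", index=prop)]
            )
            groups = groups[groups.index.isin(cnv_records.index)]
            evo = evolution_report(
                cnv_records, groups, "proportionate_amplified",
                min_strains=cfg.min_strains,
            )
            evo.to_csv(out / "evo_report.tsv", sep="\t")
            manifest["stages"]["evolution"] = {
                "groups": {g: int(n) for g, n in groups.value_counts().items()}
            }
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"[evolution] {err}") from err

    result = PipelineResult(
        config=cfg,
        count_matrix=cm,
        annotation=ann,
        truth=truth,
        ratio_table=rt,
        call_sets=call_sets,
        pooled_calls=pooled_calls,
        revised_calls=revised,
        removed_calls=removed,
        tertiles=tertiles,
        enrichment=enrichment,
        cnv_records=cnv_records,
        evo_report=evo,
        mlr_fit=mlr_fit,
        lrt=lrt,
        null_proportion_report=np_report,
        manifest=manifest,
    )
    (out / "summary.txt").write_text(summarize(result))

    # ---- manifest (hashes cover every written output) -------------------
    outputs = {}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        outputs[f.name] = _sha256(f)
    manifest["outputs"] = outputs
    hashed = {
        k: manifest[k]
        for k in ("config_sha256", "seed", "version", "stages", "outputs")
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def _pct(k: int, n: int) -> str:
    return f"{k}/{n} ({100.0 * k / n:.1f}%)" if n else f"{k}/0"


def summarize(result: PipelineResult) -> str:
    """Human-readable per-analysis summary with explicit denominators."""
    lines = ["aneudose pipeline summary", "========================="]
    for strain, cs in result.call_sets.items():
        n_called = int(len(cs.called_genes))
        line = f"{strain}: lower-expressed amplified genes {_pct(n_called, cs.n_assessed)}"
        if n_called == 0:
            line += " (FDR undefined)"
        elif cs.fdr_estimate is not None:
            line += f", permutation FDR {100 * cs.fdr_estimate:.1f}%"
        if len(cs.not_assessed):
            line += f"; {len(cs.not_assessed)} gene(s) not assessed"
        lines.append(line)
    if result.mlr_fit is not None:
        pi = result.mlr_fit.weights_
        lines.append(
            "MLR mixing proportions: "
            + ", ".join(f"{k}={v:.3f}" for k, v in pi.items())
        )
        if result.null_proportion_report is not None:
            r = result.null_proportion_report
            lines.append(
                f"MLR non-proportional {100 * r.mlr_nonproportional:.1f}% vs "
                f"LRT non-null {100 * r.lrt_nonnull:.1f}% "
                f"(|diff| {100 * r.difference:.1f} points, n={r.n_genes})"
            )
    st = result.manifest["stages"].get("filter", {})
    if st:
        lines.append(
            f"indirect-response filter removed {st['n_removed']}/{st['n_calls']} "
            f"calls ({100 * st['removal_fraction']:.1f}%)"
        )
    if result.evo_report is not None:
        for g, row in result.evo_report.iterrows():
            lines.append(
                f"evolution [{g}]: CNV fraction {row['cnv_fraction']:.3f}, "
                f"median buffering {row['median_buffering']:.2f}"
            )
    return "\n".join(lines) + "\n"
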