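"""Count-table IO, normalization and log2 ratio tables.

Raw inputs are gene-level read counts for RNA-seq and DNA-seq samples of
aneuploid and euploid strains.  Counts are normalized either by RPKM
(reads per kb of gene length per million mapped reads, optionally
recomputing library totals with the amplified chromosomes excluded) or by
a spike-in scheme in which reads from a foreign species doped in
proportion to counted cells give per-cell abundances.  Normalized
abundances are then compared between strains to give per-gene log2
relative mRNA and DNA abundances, the common currency of all downstream
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MOLECULES = ("RNA", "DNA")

SAMPLE_COLUMNS = [
    "strain",
    "molecule",
    "replicate",
    "ploidy_label",
    "spike_total",
    "cells_counted",
]

ANNOTATION_COLUMNS = ["chromosome", "length_bp", "amplified_in", "categories"]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing sample.

    ``spike_total`` is the number of reads mapping to the spike-in species
    and ``cells_counted`` the number of cells counted in the collection;
    both must be present for spike-in normalization.
    """

    name: str
    strain: str
    molecule: str
    replicate: int
    ploidy_label: str = ""
    spike_total: float | None = None
    cells_counted: float | None = None

    def __post_init__(self) -> None:
        if self.molecule not in MOLECULES:
            raise ValueError(
                f"sample {self.name!r}: molecule must be one of {MOLECULES}, "
                f"got {self.molecule!r}"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"sample {self.name!r}: replicate must be >= 1")


def samples_frame(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Stack SampleMeta records into the sample-sheet DataFrame."""
    df = pd.DataFrame(
        [
            {
                "sample": m.name,
                "strain": m.strain,
                "molecule": m.molecule,
                "replicate": int(m.replicate),
                "ploidy_label": m.ploidy_label,
                "spike_total": m.spike_total,
                "cells_counted": m.cells_counted,
            }
            for m in metas
        ]
    )
    return df.set_index("sample")


@dataclass
class CountMatrix:
    """Genes x samples integer read counts plus sample metadata.

    ``counts``: DataFrame indexed by gene_id, one column per sample.
    ``samples``: DataFrame indexed by sample name with columns
    strain / molecule / replicate / ploidy_label / spike_total /
    cells_counted.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dups[:5]}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        missing = [c for c in counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in ("strain", "molecule", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        bad = ~self.samples["molecule"].isin(MOLECULES)
        if bad.any():
            raise ValueError(
                f"invalid molecule for sample(s) {self.samples.index[bad].tolist()}"
            )
        triple = self.samples.loc[
            list(counts.columns), ["strain", "molecule", "replicate"]
        ]
        if triple.duplicated().any():
            raise ValueError(
                "every sample must have a distinct (strain, molecule, replicate)"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, strain: str, molecule: str) -> list[str]:
        sel = (self.samples["strain"] == strain) & (
            self.samples["molecule"] == molecule
        )
        sub = self.samples[sel].sort_values("replicate")
        return [s for s in sub.index if s in self.counts.columns]


@dataclass
class GeneAnnotation:
    """Per-gene chromosome, length, amplified-strain set and categories.

    ``table`` is indexed by gene_id with columns chromosome (str),
    length_bp (int), amplified_in (frozenset of strain names) and
    categories (frozenset of category names).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        t.index.name = "gene_id"
        if t.index.has_duplicates:
            raise ValueError("duplicate gene_id in annotation")
        if (t["length_bp"] < 1).any():
            raise ValueError("length_bp must be >= 1")
        for col in ("amplified_in", "categories"):
            self.table[col] = t[col].map(
                lambda v: frozenset(v) if not isinstance(v, frozenset) else v
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def lengths_kb(self, genes: pd.Index | None = None) -> pd.Series:
        t = self.table if genes is None else self.table.loc[genes]
        return t["length_bp"] / 1000.0

    def genes_on(self, chromosome: str) -> pd.Index:
        return self.table.index[self.table["chromosome"] == chromosome]

    def amplified_genes(self, strain: str) -> pd.Index:
        mask = self.table["amplified_in"].map(lambda s: strain in s)
        return self.table.index[mask]

    def unamplified_genes(self, strain: str) -> pd.Index:
        mask = self.table["amplified_in"].map(lambda s: strain not in s)
        return self.table.index[mask]

    def amplified_chromosomes(self, strain: str) -> list[str]:
        genes = self.amplified_genes(strain)
        return sorted(self.table.loc[genes, "chromosome"].unique())

    def category_map(self) -> "CategoryMap":
        genes: dict[str, set[str]] = {}
        for gid, cats in self.table["categories"].items():
            for c in cats:
                genes.setdefault(c, set()).add(gid)
        return CategoryMap({c: frozenset(g) for c, g in genes.items()})


@dataclass
class CategoryMap:
    """Gene-set map (GMT-style): category name -> member genes.

    ``localization`` marks categories describing cellular localization,
    which the indirect-response filter can skip.
    """

    genes: Mapping[str, frozenset]
    localization: frozenset = frozenset()

    def categories_of(self, gene: str) -> set[str]:
        return {c for c, g in self.genes.items() if gene in g}

    def membership(self, universe: Iterable[str]) -> pd.DataFrame:
        """Boolean genes x categories membership frame over a universe."""
        universe = pd.Index(universe)
        data = {
            c: universe.isin(list(members)) for c, members in self.genes.items()
        }
        return pd.DataFrame(data, index=universe)


@dataclass
class RatioTable:
    """Long-format per-gene log2 ratios for strain comparisons.

    ``data`` columns: gene_id, comparison_id, replicate, molecule,
    log2_ratio.  ``comparisons`` is indexed by comparison_id with
    test_strain / ref_strain.  ``dropped`` records genes excluded from a
    comparison because of zero abundance in either sample.
    """

    data: pd.DataFrame
    comparisons: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "comparison_id", "molecule", "reason"]
        )
    )

    def __post_init__(self) -> None:
        vals = self.data["log2_ratio"].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("log2 ratios must be finite")
        key = ["gene_id", "comparison_id", "replicate", "molecule"]
        if self.data.duplicated(subset=key).any():
            raise ValueError(
                "a gene may appear at most once per "
                "(comparison, replicate, molecule)"
            )

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.comparisons.index)

    def test_strain(self, comparison_id: str) -> str:
        return self.comparisons.loc[comparison_id, "test_strain"]

    def mrna(self, comparison_id: str) -> pd.DataFrame:
        """Genes x replicates matrix of log2 mRNA ratios for a comparison."""
        sub = self.data[
            (self.data["comparison_id"] == comparison_id)
            & (self.data["molecule"] == "RNA")
        ]
        return sub.pivot(index="gene_id", columns="replicate", values="log2_ratio")

    def dna(self, comparison_id: str) -> pd.Series:
        """Per-gene log2 DNA ratio (mean over DNA replicates)."""
        sub = self.data[
            (self.data["comparison_id"] == comparison_id)
            & (self.data["molecule"] == "DNA")
        ]
        return sub.groupby("gene_id")["log2_ratio"].mean()

    def subset_genes(self, genes: Iterable[str]) -> "RatioTable":
        genes = set(genes)
        return RatioTable(
            self.data[self.data["gene_id"].isin(genes)].reset_index(drop=True),
            self.comparisons.copy(),
            self.dropped,
        )


# ---------------------------------------------------------------------------
# Readers / writers (plain TSV; GMT for category maps)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    df = df.set_index("gene_id")
    for col in ("amplified_in", "categories"):
        raw = df[col].fillna("") if col in df.columns else ""
        df[col] = [
            frozenset(x for x in str(v).split(",") if x) for v in raw
        ]
    df["length_bp"] = df["length_bp"].astype(int)
    return GeneAnnotation(df[ANNOTATION_COLUMNS].copy())


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    for col in ("amplified_in", "categories"):
        out[col] = out[col].map(lambda s: ",".join(sorted(s)))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(
    counts_path: str | Path,
    samples_path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[CountMatrix, GeneAnnotation | None]:
    """Read a count TSV (gene_id + one column per sample), its sample
    sheet and optionally the gene annotation.

    Genes absent from the annotation are rejected, as are negative or
    non-integer counts and duplicate gene ids.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    cm = CountMatrix(counts, samples)
    ann = None
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        unknown = counts.index.difference(ann.gene_ids)
        if len(unknown):
            raise ValueError(
                f"{len(unknown)} gene(s) absent from annotation, "
                f"e.g. {list(unknown[:5])}"
            )
    return cm, ann


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_gmt(path: str | Path) -> CategoryMap:
    genes: dict[str, frozenset] = {}
    localization: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:50]!r}")
            name, desc = parts[0], parts[1]
            genes[name] = frozenset(g for g in parts[2:] if g)
            if "#localization" in desc:
                localization.add(name)
    return CategoryMap(genes, frozenset(localization))


def write_gmt(cmap: CategoryMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(cmap.genes):
            desc = "#localization" if name in cmap.localization else "na"
            members = "\t".join(sorted(cmap.genes[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_ratio_table(rt: RatioTable, path: str | Path, comparisons_path: str | Path | None = None) -> None:
    cols = ["gene_id", "comparison_id", "replicate", "molecule", "log2_ratio"]
    rt.data[cols].to_csv(path, sep="\t", index=False)
    if comparisons_path is not None:
        rt.comparisons.to_csv(comparisons_path, sep="\t", index_label="comparison_id")


def read_ratio_table(path: str | Path, comparisons_path: str | Path | None = None) -> RatioTable:
    data = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "comparison_id": str})
    if comparisons_path is not None:
        comparisons = pd.read_csv(comparisons_path, sep="\t", index_col=0)
    else:
        comparisons = pd.DataFrame(
            {"test_strain": "", "ref_strain": ""},
            index=pd.Index(data["comparison_id"].unique(), name="comparison_id"),
        )
    return RatioTable(data, comparisons)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def rpkm_normalize(
    cm: CountMatrix,
    ann: GeneAnnotation,
    exclude_chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Reads per kb of gene length per million mapped reads.

    ``exclude_chromosomes`` removes chromosomes from each sample's library
    total (the "RPKM excluding the amplified chromosomes" variant) while
    keeping values for their genes.
    """
    genes = cm.gene_ids
    lengths_kb = ann.lengths_kb(genes)
    if exclude_chromosomes:
        excl = set(exclude_chromosomes)
        keep = ~ann.table.loc[genes, "chromosome"].isin(excl)
    else:
        keep = pd.Series(True, index=genes)
    totals = cm.counts.loc[keep.to_numpy()].sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero library total for sample(s) {zero}")
    return cm.counts.div(lengths_kb, axis=0).div(totals / 1e6, axis=1)


def spike_in_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Per-cell abundances from spike-in reads doped per counted cell.

    Each sample is scaled by its spike reads per counted cell relative to
    the first sample; the output is invariant to the choice of reference
    up to a global constant.
    """
    factors = {}
    for s in cm.counts.columns:
        spike = cm.samples.loc[s, "spike_total"]
        cells = cm.samples.loc[s, "cells_counted"]
        if pd.isna(spike) or pd.isna(cells):
            raise ValueError(f"sample {s!r} lacks spike-in metadata")
        if spike <= 0 or cells <= 0:
            raise ValueError(
                f"sample {s!r}: spike_total and cells_counted must be > 0"
            )
        factors[s] = float(spike) / float(cells)
    ref = cm.counts.columns[0]
    scale = pd.Series({s: factors[ref] / f for s, f in factors.items()})
    return cm.counts.mul(scale, axis=1)


def log2_ratios(
    abund: pd.DataFrame,
    samples: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
) -> RatioTable:
    """Per-gene log2(test/ref) ratios for a list of sample pairs.

    ``pairs`` holds (test_sample, ref_sample, comparison_id) triples; the
    molecule and replicate number are taken from the test sample's
    metadata.  Genes with zero abundance in either sample of a pair are
    dropped from that pair and listed in the drop report.
    """
    rows = []
    dropped = []
    comp_meta: dict[str, tuple[str, str]] = {}
    for test, ref, comp in pairs:
        mol = samples.loc[test, "molecule"]
        if samples.loc[ref, "molecule"] != mol:
            raise ValueError(
                f"pair ({test}, {ref}): molecules differ within a comparison pair"
            )
        rep = int(samples.loc[test, "replicate"])
        strains = (samples.loc[test, "strain"], samples.loc[ref, "strain"])
        if comp in comp_meta and comp_meta[comp] != strains:
            raise ValueError(f"comparison {comp!r} mixes strain pairs")
        comp_meta[comp] = strains
        a = abund[test]
        b = abund[ref]
        keep = (a > 0) & (b > 0)
        for g in abund.index[~keep]:
            dropped.append(
                {"gene_id": g, "comparison_id": comp, "molecule": mol,
                 "reason": "zero_abundance"}
            )
        vals = np.log2(a[keep] / b[keep])
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": abund.index[keep],
                    "comparison_id": comp,
                    "replicate": rep,
                    "molecule": mol,
                    "log2_ratio": vals.to_numpy(),
                }
            )
        )
    data = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene_id", "comparison_id", "replicate", "molecule", "log2_ratio"]
    )
    comparisons = pd.DataFrame(
        [
            {"comparison_id": c, "test_strain": t, "ref_strain": r}
            for c, (t, r) in comp_meta.items()
        ]
    ).set_index("comparison_id")
    drop_df = pd.DataFrame(
        dropped, columns=["gene_id", "comparison_id", "molecule", "reason"]
    )
    return RatioTable(data, comparisons, drop_df)


def distribution_center(
    rt: RatioTable,
    genes: Iterable[str] | None = None,
    molecule: str = "RNA",
    comparison_id: str | None = None,
) -> float:
    """Mean of log2 ratios over a gene subset — a normalization
    diagnostic (centers of unamplified genes should sit near 0), not a
    correction."""
    sub = rt.data[rt.data["molecule"] == molecule]
    if comparison_id is not None:
        sub = sub[sub["comparison_id"] == comparison_id]
    if genes is not None:
        sub = sub[sub["gene_id"].isin(set(genes))]
    if sub.empty:
        raise ValueError("empty gene subset for distribution center")
    return float(sub["log2_ratio"].mean())
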