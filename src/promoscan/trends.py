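"""Trend clustering of an FPKM matrix and selection of trend gene lists.

Genes are clustered by hierarchical agglomeration (Euclidean distance,
complete linkage) on their replicate-mean expression profile per
(genotype, treatment) cell — four values per gene in a 2x2 design —
row-z-scored so that clusters group by trend shape rather than expression
magnitude. Clusters are then labeled by their mean flooded-vs-control
log2 fold change in each genotype:

* ``up_A_enhanced``   — induced by flooding, with a strictly larger fold
  change in the reference genotype (the wild-type analog) than in the
  other genotype;
* ``down_A_enhanced`` — the mirrored repressed group;
* ``other``           — everything else.

The two labeled gene lists are the foreground sets fed to the promoter
motif enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ExpressionMatrix",
    "TrendClusterSet",
    "cluster_genes",
    "label_trends",
    "cluster_gene_lists",
]

TREND_LABELS = ("up_A_enhanced", "down_A_enhanced", "other")


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with its 2x2(xR) design.

    ``values``: DataFrame, genes as index, samples as columns, all finite
    and >= 0. ``design``: DataFrame with columns ``sample, genotype,
    treatment, replicate`` covering every column of ``values``; every
    (genotype, treatment) cell needs at least one replicate.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (v.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        d = self.design.set_index("sample") if "sample" in self.design.columns else self.design
        missing = set(v.columns) - set(d.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")
        self._design_ix = d.loc[list(v.columns)]
        cells = self._design_ix.groupby(["genotype", "treatment"]).size()
        genos = sorted(self._design_ix["genotype"].unique())
        treats = self.treatments
        if len(genos) != 2 or len(treats) != 2:
            raise ValueError("design must have exactly 2 genotypes and 2 treatments")
        for g in genos:
            for t in treats:
                if (g, t) not in cells.index:
                    raise ValueError(f"design cell ({g}, {t}) has no replicates")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self._design_ix["genotype"].unique())

    @property
    def treatments(self) -> list[str]:
        """(control-like, treated-like) — 'control' first if present, else sorted."""
        t = sorted(self._design_ix["treatment"].unique())
        if "control" in t:
            t = ["control"] + [x for x in t if x != "control"]
        return t

    def cell_means(self) -> pd.DataFrame:
        """Replicate-mean FPKM per gene per (genotype, treatment) cell."""
        cols = {}
        for g in self.genotypes:
            for t in self.treatments:
                samples = self._design_ix.index[
                    (self._design_ix["genotype"] == g) & (self._design_ix["treatment"] == t)]
                cols[(g, t)] = self.values[list(samples)].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "treatment"])
        return out

    def log2fc(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Per-gene log2((flooded+pc)/(control+pc)) per genotype."""
        means = self.cell_means()
        ctrl, trt = self.treatments
        out = {}
        for g in self.genotypes:
            out[g] = np.log2((means[(g, trt)] + pseudocount) / (means[(g, ctrl)] + pseudocount))
        return pd.DataFrame(out)

    @classmethod
    def from_tsv(cls, matrix_path, design_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        return cls(values, design)

    def to_tsv(self, matrix_path, design_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.design.to_csv(design_path, sep="\t", index=False)


@dataclass
class TrendClusterSet:
    """Cluster assignments plus the linkage tree and labeling that produced them."""

    assignments: pd.Series                 # gene id -> cluster index (1-based)
    linkage_matrix: np.ndarray             # scipy linkage record of merge heights
    params: dict = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)   # cluster index -> trend label
    cluster_log2fc: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())

    def genes_in(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def to_frame(self) -> pd.DataFrame:
        df = self.assignments.rename("cluster").to_frame()
        df.index.name = "gene"
        df["label"] = [self.labels.get(c, "") for c in df["cluster"]]
        return df.reset_index()


def _profiles(matrix: ExpressionMatrix) -> np.ndarray:
    """Row-z-scored replicate-mean profiles (constant rows become zeros)."""
    x = matrix.cell_means().values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[~np.isfinite(z)] = 0.0
    return z


def cluster_genes(matrix: ExpressionMatrix, n_clusters: int) -> TrendClusterSet:
    """Agglomerative (Euclidean, complete-linkage) clustering into ``n_clusters``.

    Operates on row-z-scored replicate-mean profiles so clusters reflect
    expression trend, not magnitude. Deterministic for a given input.
    """
    n_genes = len(matrix.values)
    if not 1 <= n_clusters <= n_genes:
        raise ValueError(f"n_clusters must be in [1, {n_genes}], got {n_clusters}")
    z = _profiles(matrix)
    if n_genes == 1:
        assign = np.array([1])
        lk = np.empty((0, 4))
    else:
        lk = linkage(z, method="complete", metric="euclidean")
        assign = fcluster(lk, t=n_clusters, criterion="maxclust")
    assignments = pd.Series(assign, index=matrix.values.index, name="cluster")
    return TrendClusterSet(assignments, lk,
                           params={"distance": "euclidean", "method": "complete",
                                   "n_clusters": n_clusters, "standardized": True})


def label_trends(
    clusters: TrendClusterSet,
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    reference_genotype: str | None = None,
) -> TrendClusterSet:
    """Label each cluster by its mean fold-change pattern.

    ``reference_genotype`` is the wild-type analog whose response must be
    the stronger one (defaults to the alphabetically first genotype).
    Per cluster, the per-gene log2((flooded+pc)/(control+pc)) values are
    averaged per genotype; strict inequalities decide the label, so a
    cluster with exactly equal responses is ``other``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    genos = matrix.genotypes
    ref = reference_genotype if reference_genotype is not None else genos[0]
    if ref not in genos:
        raise ValueError(f"reference genotype {ref!r} not in design")
    alt = [g for g in genos if g != ref][0]
    fc = matrix.log2fc(pseudocount)
    labels: dict[int, str] = {}
    rows = {}
    for c in sorted(clusters.assignments.unique()):
        genes = clusters.genes_in(c)
        fc_ref = float(fc.loc[genes, ref].mean())
        fc_alt = float(fc.loc[genes, alt].mean())
        if fc_ref > 0 and fc_ref > fc_alt:
            lab = "up_A_enhanced"
        elif fc_ref < 0 and fc_ref < fc_alt:
            lab = "down_A_enhanced"
        else:
            lab = "other"
        labels[int(c)] = lab
        rows[int(c)] = (fc_ref, fc_alt, lab)
    summary = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"log2fc_{ref}", f"log2fc_{alt}", "label"])
    summary.index.name = "cluster"
    params = dict(clusters.params, pseudocount=pseudocount, reference_genotype=ref)
    return TrendClusterSet(clusters.assignments, clusters.linkage_matrix, params,
                           labels, summary)


def cluster_gene_lists(labeled: TrendClusterSet) -> dict[str, list[str]]:
    """Gene lists for the two selected trend labels; 'other' genes excluded."""
    out: dict[str, list[str]] = {"up_A_enhanced": [], "down_A_enhanced": []}
    for gene, c in labeled.assignments.items():
        lab = labeled.labels.get(int(c), "other")
        if lab in out:
            out[lab].append(gene)
    return out
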