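"""Synthetic genomes, planted promoter motifs, and expression matrices.

Every downstream stage of the pipeline (promoter extraction, trend
clustering, motif enrichment) is testable against known ground truth using
the generators here, with no external download. The generators are pure
functions of (spec, seed): identical inputs give byte-identical outputs.

The toy genome is laid out so that each gene is flanked by intergenic
spacers longer than the promoter window, which guarantees promoters never
overlap neighbouring genes and isolates promoter-extraction tests from any
overlap-trimming policy. The expression generator plants the two trend
groups the study design contrasts — genes induced by flooding with a larger
fold change in genotype A (the wild-type analog) than in genotype B (the
ABA-deficient analog), and the mirrored repressed group — on top of
multiplicative log-normal noise on an FPKM-like scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .promoters import GeneModel

__all__ = [
    "SyntheticGenomeSpec",
    "MotifPlantingSpec",
    "SyntheticExpressionSpec",
    "generate_genome",
    "plant_motifs",
    "generate_expression",
    "write_fasta",
    "write_gff3",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a toy multi-contig genome with evenly spaced genes.

    Each contig is ``intergenic_len + genes_per_contig * (gene_len +
    intergenic_len)`` bases: a spacer, then alternating gene/spacer blocks.
    ``intergenic_len`` must exceed the promoter window length used downstream
    for promoters to be full-length and non-overlapping.
    """

    n_contigs: int = 5
    genes_per_contig: int = 20
    intergenic_len: int = 1200
    gene_len: int = 600
    gc_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 0:
            raise ValueError("n_contigs must be >= 0")
        if self.n_contigs > 0 and (self.genes_per_contig <= 0 or self.intergenic_len <= 0
                                   or self.gene_len <= 0):
            raise ValueError("genes_per_contig, intergenic_len and gene_len must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")

    @property
    def contig_len(self) -> int:
        return self.intergenic_len + self.genes_per_contig * (self.gene_len + self.intergenic_len)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate contig sequences and gene models for ``spec``.

    Returns ``(contigs, genes)`` where ``contigs`` maps contig name to
    sequence and each gene is a :class:`GeneModel` with biotype
    ``protein_coding`` and TSS at its 5'-most base (start for + strand
    genes, end for - strand genes, 1-based).
    """
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(spec.n_contigs):
        name = f"contig{c + 1:02d}"
        contigs[name] = _random_dna(rng, spec.contig_len, spec.gc_fraction)
        pos = spec.intergenic_len  # 0-based start of the next gene block
        for g in range(spec.genes_per_contig):
            start = pos + 1  # 1-based inclusive
            end = pos + spec.gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            genes.append(GeneModel(
                gene_id=f"g{c + 1:02d}_{g + 1:04d}", contig=name, strand=strand,
                tss=tss, biotype="protein_coding", start=start, end=end,
            ))
            pos = end + spec.intergenic_len
    return contigs, genes


@dataclass(frozen=True)
class MotifPlantingSpec:
    """A single motif planted into promoter sequences at per-promoter rates.

    Each foreground promoter independently receives one planted copy with
    probability ``foreground_presence_rate`` (background promoters with
    ``background_presence_rate``), at a uniform-random offset. Planting
    overwrites exactly ``len(motif)`` bases, so sequence lengths never
    change. The planted copy may coincide with or create chance occurrences
    elsewhere; the returned log records planted copies only.
    """

    motif: str
    foreground_gene_ids: frozenset[str] = frozenset()
    foreground_presence_rate: float = 0.5
    background_presence_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motif or any(b not in "ACGT" for b in self.motif):
            raise ValueError(f"motif must be a non-empty string over ACGT, got {self.motif!r}")
        for r in (self.foreground_presence_rate, self.background_presence_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("presence rates must lie in [0, 1]")
        object.__setattr__(self, "foreground_gene_ids", frozenset(self.foreground_gene_ids))


def plant_motifs(
    sequences: Mapping[str, str], planting: MotifPlantingSpec
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Plant ``planting.motif`` into ``sequences`` (gene id -> sequence).

    Returns the modified sequences and the ground-truth log of
    ``(gene_id, offset)`` plantings (0-based offset into the sequence).
    Genes are visited in sorted id order so output is a pure function of
    (sequences, spec).
    """
    k = len(planting.motif)
    missing = planting.foreground_gene_ids - set(sequences)
    if missing:
        raise KeyError(f"foreground gene ids absent from sequences: {sorted(missing)[:5]}")
    for gid, seq in sequences.items():
        if len(seq) < k:
            raise ValueError(f"promoter {gid} shorter than motif ({len(seq)} < {k})")
    rng = np.random.default_rng(planting.seed)
    out: dict[str, str] = dict(sequences)
    log: list[tuple[str, int]] = []
    for gid in sorted(sequences):
        rate = (planting.foreground_presence_rate
                if gid in planting.foreground_gene_ids
                else planting.background_presence_rate)
        if rng.random() < rate:
            seq = out[gid]
            off = int(rng.integers(0, len(seq) - k + 1))
            out[gid] = seq[:off] + planting.motif + seq[off + k:]
            log.append((gid, off))
    return out, log


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """FPKM-like expression matrix for a 2 genotype x 2 treatment design.

    ``trend_assignments`` maps gene id to ``up_A_enhanced``,
    ``down_A_enhanced`` or ``null``. Up-trend genes get a flooded/control
    log2 fold change of +log2fc_A in genotype A and +log2fc_B in genotype B;
    down-trend genes get the negated values; null genes have no treatment
    effect. Noise is multiplicative log-normal with standard deviation
    ``noise_sd_log`` on the natural-log scale, applied independently per
    measurement, so all values stay non-negative.
    """

    n_genes: int = 300
    genotypes: tuple[str, str] = ("A", "B")
    treatments: tuple[str, str] = ("control", "flooded")
    n_replicates: int = 3
    trend_assignments: Mapping[str, str] = field(default_factory=dict)
    base_expression: float = 20.0
    log2fc_A: float = 2.0
    log2fc_B: float = 1.0
    noise_sd_log: float = 0.1
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be non-negative")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be positive")
        ids = self.gene_ids
        if ids is None:
            ids = tuple(f"gene{i + 1:05d}" for i in range(self.n_genes))
        else:
            ids = tuple(ids)
            if len(ids) != self.n_genes:
                raise ValueError("gene_ids length must equal n_genes")
        object.__setattr__(self, "gene_ids", ids)
        bad = set(self.trend_assignments) - set(ids)
        if bad:
            raise ValueError(f"trend_assignments refer to unknown genes: {sorted(bad)[:5]}")
        bad_labels = set(self.trend_assignments.values()) - {"up_A_enhanced", "down_A_enhanced", "null"}
        if bad_labels:
            raise ValueError(f"unknown trend labels: {sorted(bad_labels)}")


def generate_expression(spec: SyntheticExpressionSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(matrix, design)`` for ``spec``.

    ``matrix`` is genes x samples; ``design`` has one row per sample with
    columns ``sample, genotype, treatment, replicate``.
    """
    geno_a, geno_b = spec.genotypes
    ctrl, trt = spec.treatments
    samples = []
    for geno in spec.genotypes:
        for treat in spec.treatments:
            for r in range(1, spec.n_replicates + 1):
                samples.append((f"{geno}_{treat}_rep{r}", geno, treat, r))
    design = pd.DataFrame(samples, columns=["sample", "genotype", "treatment", "replicate"])

    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, len(samples)
    # signed log2 fold change per gene per genotype
    fc = np.zeros((n, 2))  # columns: genotype A, genotype B
    for i, gid in enumerate(spec.gene_ids):
        trend = spec.trend_assignments.get(gid, "null")
        if trend == "up_A_enhanced":
            fc[i] = (spec.log2fc_A, spec.log2fc_B)
        elif trend == "down_A_enhanced":
            fc[i] = (-spec.log2fc_A, -spec.log2fc_B)
    mean = np.empty((n, m))
    for j, (_, geno, treat, _) in enumerate(samples):
        col_fc = fc[:, 0] if geno == geno_a else fc[:, 1]
        mean[:, j] = spec.base_expression * np.where(treat == trt, 2.0 ** col_fc, 1.0)
    noise = np.exp(rng.normal(0.0, spec.noise_sd_log, size=(n, m))) if spec.noise_sd_log > 0 else 1.0
    values = mean * noise
    matrix = pd.DataFrame(values, index=list(spec.gene_ids), columns=[s[0] for s in samples])
    matrix.index.name = "gene"
    return matrix, design


def write_fasta(contigs: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path, source: str = "promoscan") -> None:
    """Write gene features as GFF3 (1-based inclusive, ID attribute set)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.start is None or g.end is None:
                start = end = g.tss
            else:
                start, end = g.start, g.end
            fh.write(f"{g.contig}\t{source}\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};biotype={g.biotype}\n")
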