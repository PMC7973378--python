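"""End-to-end orchestration: inputs -> promoters -> trends -> enrichment -> annotation.

A run either loads real inputs (genome FASTA + GFF3, expression and design
TSVs) or synthesizes a complete dataset with known ground truth — exactly
one of the two. Every intermediate artifact is written to the output
directory together with a machine-readable manifest; rerunning with the
same config and seed reproduces the stage outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import importlib.resources
import pandas as pd

from . import __version__
from .annotation import annotate_records, load_elements
from .enrichment import count_motifs, enrichment_fraction, filter_enriched, records_to_frame, score_motifs
from .promoters import PromoterSet, extract_promoters, read_genome_fasta, read_gff3
from .synthetic import (MotifPlantingSpec, SyntheticExpressionSpec, SyntheticGenomeSpec,
                        generate_expression, generate_genome, plant_motifs, write_fasta, write_gff3)
from .trends import ExpressionMatrix, cluster_gene_lists, cluster_genes, label_trends

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "verify_tables"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run. Defaults follow the study parameters:
    1,000-bp promoters, hexamers, enrichment threshold 1.1, BH at 0.05."""

    out_dir: str = "promoscan_out"
    seed: int = 0

    # real inputs (all four required together)
    genome_fasta: str | None = None
    gff3: str | None = None
    expression_tsv: str | None = None
    design_tsv: str | None = None

    # synthetic mode
    synthetic: bool = False
    n_contigs: int = 5
    genes_per_contig: int = 40
    intergenic_len: int = 1200
    gene_len: int = 600
    gc_fraction: float = 0.38
    planted_motif: str | None = None
    fg_presence: float = 0.5
    bg_presence: float = 0.1
    n_up: int = 50
    n_down: int = 50
    log2fc_a: float = 2.0
    log2fc_b: float = 1.0
    noise_sd_log: float = 0.1
    n_replicates: int = 3
    base_expression: float = 20.0

    # analysis parameters
    promoter_length: int = 1000
    biotype: str = "protein_coding"
    k: int = 6
    mode: str = "presence"
    min_enrichment: float = 1.1
    alpha: float = 0.05
    n_clusters: int = 8
    pseudocount: float = 1.0
    elements: str | None = None
    keep_unmatched: bool = False

    def __post_init__(self) -> None:
        real = [self.genome_fasta, self.gff3, self.expression_tsv, self.design_tsv]
        have_real = any(x is not None for x in real)
        if self.synthetic and have_real:
            raise ValueError("config must name either real inputs or a synthetic block, not both")
        if not self.synthetic:
            if not all(x is not None for x in real):
                raise ValueError("non-synthetic runs need genome_fasta, gff3, "
                                 "expression_tsv and design_tsv")

    _BOOLS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat key = value config file; keyword overrides win."""
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for key, val in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key].type
            if "bool" in ftype:
                kwargs[key] = cls._BOOLS[val.lower()]
            elif "int" in ftype:
                kwargs[key] = int(val)
            elif "float" in ftype:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reraise with stage context
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("inputs")
def _prepare_inputs(cfg: PipelineConfig, out: Path):
    """Synthesize or load genome, annotation, expression and design."""
    if cfg.synthetic:
        gspec = SyntheticGenomeSpec(
            n_contigs=cfg.n_contigs, genes_per_contig=cfg.genes_per_contig,
            intergenic_len=cfg.intergenic_len, gene_len=cfg.gene_len,
            gc_fraction=cfg.gc_fraction, seed=cfg.seed)
        if gspec.intergenic_len <= cfg.promoter_length:
            raise ValueError("intergenic_len must exceed promoter_length in synthetic mode")
        contigs, genes = generate_genome(gspec)
        write_fasta(contigs, out / "genome.fa")
        write_gff3(genes, out / "genes.gff3")
        gene_ids = [g.gene_id for g in genes]
        n_up, n_down = cfg.n_up, cfg.n_down
        if n_up + n_down > len(gene_ids):
            raise ValueError("n_up + n_down exceeds the number of synthetic genes")
        trend = {g: "up_A_enhanced" for g in gene_ids[:n_up]}
        trend.update({g: "down_A_enhanced" for g in gene_ids[n_up:n_up + n_down]})
        espec = SyntheticExpressionSpec(
            n_genes=len(gene_ids), gene_ids=tuple(gene_ids), trend_assignments=trend,
            n_replicates=cfg.n_replicates, base_expression=cfg.base_expression,
            log2fc_A=cfg.log2fc_a, log2fc_B=cfg.log2fc_b,
            noise_sd_log=cfg.noise_sd_log, seed=cfg.seed + 1)
        matrix_df, design = generate_expression(espec)
        matrix_df.to_csv(out / "expression.tsv", sep="\t")
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        truth = {"up_A_enhanced": gene_ids[:n_up],
                 "down_A_enhanced": gene_ids[n_up:n_up + n_down]}
        return contigs, genes, ExpressionMatrix(matrix_df, design), truth
    contigs = read_genome_fasta(cfg.genome_fasta)
    genes = read_gff3(cfg.gff3)
    matrix = ExpressionMatrix.from_tsv(cfg.expression_tsv, cfg.design_tsv)
    return contigs, genes, matrix, None


@_stage("promoters")
def _promoter_stage(cfg: PipelineConfig, out: Path, contigs, genes, truth):
    promoters = extract_promoters(contigs, genes, length=cfg.promoter_length,
                                  biotype_filter=cfg.biotype)
    if cfg.synthetic and cfg.planted_motif:
        planting = MotifPlantingSpec(
            motif=cfg.planted_motif,
            foreground_gene_ids=frozenset(truth["up_A_enhanced"]),
            foreground_presence_rate=cfg.fg_presence,
            background_presence_rate=cfg.bg_presence, seed=cfg.seed + 2)
        seqs, log = plant_motifs(promoters.sequences(), planting)
        promoters = promoters.with_sequences(seqs)
        pd.DataFrame(log, columns=["gene_id", "offset"]).to_csv(
            out / "planted_motifs.tsv", sep="\t", index=False)
    promoters.to_fasta(out / "promoters.fa")
    promoters.lengths_table().to_csv(out / "promoter_lengths.tsv", sep="\t", index=False)
    return promoters


@_stage("trends")
def _trend_stage(cfg: PipelineConfig, out: Path, matrix: ExpressionMatrix):
    clusters = cluster_genes(matrix, cfg.n_clusters)
    labeled = label_trends(clusters, matrix, pseudocount=cfg.pseudocount)
    labeled.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
    lists = cluster_gene_lists(labeled)
    for label, genes in lists.items():
        (out / f"genes_{label}.txt").write_text("".join(g + "\n" for g in genes))
    return labeled, lists


@_stage("enrichment")
def _enrichment_stage(cfg: PipelineConfig, out: Path, promoters: PromoterSet,
                      lists: dict[str, list[str]]):
    table = load_elements(cfg.elements)
    results = {}
    for label, fg in lists.items():
        fg = [g for g in fg if g in promoters]
        if not fg:
            logger.warning("label %s: empty foreground, skipped", label)
            continue
        counts = count_motifs(promoters, fg, k=cfg.k, mode=cfg.mode)
        records = score_motifs(counts, cfg.min_enrichment, cfg.alpha)
        records_to_frame(records).to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False)
        kept = filter_enriched(records, cfg.min_enrichment, cfg.alpha)
        annotated = annotate_records(kept, table, keep_unmatched=cfg.keep_unmatched)
        records_to_frame(annotated).to_csv(out / f"annotated_{label}.tsv", sep="\t", index=False)
        results[label] = {"n_motifs": len(records), "n_pass": len(kept),
                          "n_annotated": len(annotated),
                          "passing_motifs": [r.motif for r in kept]}
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, genes, matrix, truth = _prepare_inputs(config, out)
    promoters = _promoter_stage(config, out, contigs, genes, truth)
    labeled, lists = _trend_stage(config, out, matrix)
    results = _enrichment_stage(config, out, promoters, lists)
    manifest = {
        "promoscan_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_contigs": len(contigs),
        "n_genes": len(genes),
        "n_promoters": len(promoters),
        "n_clusters": labeled.n_clusters,
        "cluster_labels": {str(k): v for k, v in labeled.labels.items()},
        "gene_list_sizes": {k: len(v) for k, v in lists.items()},
        "enrichment": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def verify_tables(counts_tsv=None, tolerance: float = 5e-7) -> dict:
    """Recompute the enrichment fraction for a transcribed count fixture.

    The fixture TSV needs columns motif, k_fg, K_fg, n_bg, N_bg,
    expected_enrichment. Returns a report with the max absolute deviation
    and the list of failing rows (|computed - expected| > tolerance).
    """
    if counts_tsv is None:
        ref = importlib.resources.files("promoscan.data") / "reported_enrichment.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(counts_tsv, sep="\t")
    required = ["motif", "k_fg", "K_fg", "n_bg", "N_bg", "expected_enrichment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fixture is missing columns {missing}")
    failures = []
    max_diff = 0.0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        try:
            computed = enrichment_fraction(int(row.k_fg), int(row.K_fg),
                                           int(row.n_bg), int(row.N_bg))
            expected = float(row.expected_enrichment)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed fixture row at line {i}: {exc}") from exc
        diff = abs(computed - expected)
        max_diff = max(max_diff, diff)
        if diff > tolerance:
            failures.append({"line": i, "motif": row.motif,
                             "computed": computed, "expected": expected})
    return {"n_rows": len(df), "max_abs_diff": max_diff, "tolerance": tolerance,
            "failures": failures, "ok": not failures}
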