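"""Fixed-length promoter extraction from genome FASTA + GFF3 annotation.

A promoter here is the window of up to ``L`` bases (default 1000)
immediately 5' of a gene's transcription start site, excluding the TSS base
itself, reported 5'->3' relative to the gene: minus-strand promoters are
reverse-complemented. Windows truncated at a contig edge are retained at
their actual length; genes whose window is empty (TSS at the very edge) are
skipped with a warning rather than failing the run.

Internally coordinates are handled 0-based half-open; GFF3 input/output
converts at the boundary (GFF3 is 1-based inclusive). Soft-masked
(lowercase) bases are uppercased on read; Ns are preserved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

from ._dna import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PromoterRecord",
    "PromoterSet",
    "read_genome_fasta",
    "read_gff3",
    "extract_promoters",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: where its promoter anchors.

    ``tss`` is the 1-based genomic coordinate of the gene's 5'-most base on
    its strand (the first transcribed base). ``start``/``end`` are the
    gene's 1-based inclusive span when known (used only for GFF3 output).
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    biotype: str = "protein_coding"
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1 (1-based), got {self.tss}")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    contig: str
    start: int  # 1-based inclusive genomic start of the source interval
    end: int    # 1-based inclusive genomic end
    strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        return f"{self.gene_id}|{self.contig}:{self.start}-{self.end}({self.strand})"


_HEADER_RE = re.compile(r"^(?P<gid>[^|]+)\|(?P<contig>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


@dataclass
class PromoterSet:
    """Gene-id-keyed collection of promoter sequences with provenance."""

    length_target: int
    records: dict[str, PromoterRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self.records[gene_id]

    def sequences(self) -> dict[str, str]:
        return {gid: r.sequence for gid, r in self.records.items()}

    def with_sequences(self, sequences: Mapping[str, str]) -> "PromoterSet":
        """Copy of this set with sequences replaced (e.g. after motif planting)."""
        recs = {}
        for gid, rec in self.records.items():
            seq = sequences[gid]
            if len(seq) != rec.length:
                raise ValueError(f"replacement sequence for {gid} changes length")
            recs[gid] = PromoterRecord(gid, seq, rec.contig, rec.start, rec.end, rec.strand)
        return PromoterSet(self.length_target, recs)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for rec in self.records.values():
                fh.write(f">{rec.header}\n")
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path, length_target: int = 1000) -> "PromoterSet":
        records: dict[str, PromoterRecord] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _HEADER_RE.match(rec.id)
            if m:
                records[m["gid"]] = PromoterRecord(
                    m["gid"], str(rec.seq).upper(), m["contig"],
                    int(m["start"]), int(m["end"]), m["strand"])
            else:
                # plain headers: keep the id, provenance unknown
                records[rec.id] = PromoterRecord(rec.id, str(rec.seq).upper(), "?", 1, len(rec.seq), "+")
        return cls(length_target, records)

    def lengths_table(self):
        import pandas as pd
        return pd.DataFrame(
            [(r.gene_id, r.length, r.contig, r.start, r.end, r.strand)
             for r in self.records.values()],
            columns=["gene_id", "length", "contig", "start", "end", "strand"])


def read_genome_fasta(path) -> dict[str, str]:
    """Read a multi-contig FASTA into {contig: uppercased sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3.

    One model per ``gene`` feature. When a gene has mRNA children, the TSS
    is the 5'-most mRNA start on the gene's strand; otherwise the gene's
    own 5' end. Biotype comes from a ``biotype``/``gene_biotype`` attribute
    when present, defaulting to ``protein_coding``.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        mrna_starts = [(c.start, c.end) for c in db.children(feat, featuretype="mRNA")]
        if feat.strand == "+":
            tss = min(s for s, _ in mrna_starts) if mrna_starts else feat.start
        else:
            tss = max(e for _, e in mrna_starts) if mrna_starts else feat.end
        biotype = (feat.attributes.get("biotype") or feat.attributes.get("gene_biotype")
                   or ["protein_coding"])[0]
        gid = (feat.attributes.get("ID") or [feat.id])[0]
        genes.append(GeneModel(gene_id=gid, contig=feat.seqid, strand=feat.strand,
                               tss=tss, biotype=biotype, start=feat.start, end=feat.end))
    return genes


def extract_promoters(
    genome: Mapping[str, str],
    annotation: Iterable[GeneModel],
    length: int = 1000,
    biotype_filter: str | None = "protein_coding",
) -> PromoterSet:
    """Extract up-to-``length``-bp promoters upstream of each gene's TSS.

    For a + strand gene with TSS t (1-based) the promoter is the genomic
    interval [max(1, t-length), t-1] on the forward strand; for a - strand
    gene it is the reverse complement of [t+1, min(contig_end, t+length)].
    The TSS base itself is excluded. Genes failing ``biotype_filter`` are
    skipped silently; genes with an empty window are skipped with a logged
    warning.
    """
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    records: dict[str, PromoterRecord] = {}
    for gene in annotation:
        if biotype_filter is not None and gene.biotype != biotype_filter:
            continue
        if gene.contig not in genome:
            raise KeyError(f"gene {gene.gene_id}: contig {gene.contig!r} not in genome")
        contig_seq = genome[gene.contig]
        clen = len(contig_seq)
        if gene.tss > clen:
            raise ValueError(f"gene {gene.gene_id}: TSS {gene.tss} beyond contig end {clen}")
        if gene.gene_id in records:
            raise ValueError(f"duplicate gene id {gene.gene_id} in annotation")
        if gene.strand == "+":
            start, end = max(1, gene.tss - length), gene.tss - 1
            if end < start:
                logger.warning("gene %s: empty promoter window at contig edge, skipped", gene.gene_id)
                continue
            seq = contig_seq[start - 1:end].upper()
        else:
            start, end = gene.tss + 1, min(clen, gene.tss + length)
            if end < start:
                logger.warning("gene %s: empty promoter window at contig edge, skipped", gene.gene_id)
                continue
            seq = revcomp(contig_seq[start - 1:end].upper())
        records[gene.gene_id] = PromoterRecord(gene.gene_id, seq, gene.contig, start, end, gene.strand)
    return PromoterSet(length, records)
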