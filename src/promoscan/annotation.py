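"""Matching enriched hexamers against a table of known plant cis-elements.

The bundled table is a curated, PLACE-style snapshot of plant
cis-regulatory elements (G-box, ABRE, ACGT desiccation elements, W-box,
Mem1/CACT modules, CuRE/GTAC cores, site II, rolD, legA CAAT, ...). Rows
carry an IUPAC pattern, an element name, a free-text description and a
source tag distinguishing consensus-core rows from curated
hexamer-to-element assignments. The table is user-replaceable.

Matching semantics: a motif matches a row if the row's pattern occurs as a
substring of the motif under IUPAC degeneracy, or — for patterns longer
than the motif — if the motif occurs within the pattern. Matching is on
the given strand; reverse-complement matching is available via a flag but
off by default, consistent with strand-specific counting upstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import pandas as pd

from ._dna import IUPAC, revcomp
from .enrichment import EnrichmentRecord

__all__ = [
    "CisElement",
    "CisElementTable",
    "load_elements",
    "match_motif",
    "annotate_records",
]


@dataclass(frozen=True)
class CisElement:
    pattern: str
    element_name: str
    description: str
    source: str = ""


@dataclass(frozen=True)
class CisElementTable:
    rows: tuple[CisElement, ...]

    def __post_init__(self) -> None:
        for row in self.rows:
            if not row.pattern:
                raise ValueError(f"empty pattern for element {row.element_name!r}")
            bad = [c for c in row.pattern if c not in IUPAC]
            if bad:
                raise ValueError(
                    f"invalid IUPAC character(s) {bad} in pattern {row.pattern!r} "
                    f"(element {row.element_name!r})")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @classmethod
    def from_tsv(cls, path) -> "CisElementTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"pattern", "element_name", "description"}
        if not required <= set(df.columns):
            raise ValueError(f"element table must have columns {sorted(required)}")
        rows = tuple(
            CisElement(r.pattern.upper(), r.element_name, r.description,
                       getattr(r, "source", ""))
            for r in df.itertuples(index=False))
        return cls(rows)


def load_elements(path: str | Path | None = None) -> CisElementTable:
    """Load a cis-element table; default is the bundled snapshot."""
    if path is not None:
        return CisElementTable.from_tsv(path)
    ref = importlib.resources.files("promoscan.data") / "place_elements.tsv"
    with importlib.resources.as_file(ref) as p:
        return CisElementTable.from_tsv(p)


def _compatible(a: str, b: str) -> bool:
    """Two IUPAC characters are compatible if their base sets intersect."""
    return not IUPAC[a].isdisjoint(IUPAC[b])


def _contains(seq: str, pat: str) -> bool:
    """Does any window of ``seq`` match ``pat`` position-wise under IUPAC?"""
    n, m = len(seq), len(pat)
    for i in range(n - m + 1):
        if all(_compatible(seq[i + j], pat[j]) for j in range(m)):
            return True
    return False


def match_motif(motif: str, table: CisElementTable,
                reverse_complement: bool = False) -> list[CisElement]:
    """All table rows matching ``motif`` (a concrete ACGT k-mer).

    A row matches if the motif contains the pattern (IUPAC-degenerate
    substring) or, for patterns longer than the motif, the pattern contains
    the motif. With ``reverse_complement=True`` the motif's reverse
    complement is also tried.
    """
    bad = [c for c in motif if c not in "ACGT"]
    if bad:
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    queries = [motif] + ([revcomp(motif)] if reverse_complement else [])
    hits = []
    for row in table:
        matched = False
        for q in queries:
            if len(row.pattern) <= len(q):
                matched = _contains(q, row.pattern)
            else:
                matched = _contains(row.pattern, q)
            if matched:
                break
        if matched:
            hits.append(row)
    return hits


def annotate_records(records: list[EnrichmentRecord],
                     table: CisElementTable | None = None,
                     keep_unmatched: bool = False,
                     reverse_complement: bool = False) -> list[EnrichmentRecord]:
    """Attach cis-element annotations to enrichment records.

    Each record's annotation is the matched element names/descriptions
    joined in table order. By default records with no match are dropped
    (only positively matching motifs are reported); ``keep_unmatched=True``
    keeps them with an empty annotation. Statistics fields are never
    modified.
    """
    if table is None:
        table = load_elements()
    out: list[EnrichmentRecord] = []
    for rec in records:
        hits = match_motif(rec.motif, table, reverse_complement=reverse_complement)
        if hits:
            ann = "; ".join(f"{h.element_name}: {h.description}" for h in hits)
            out.append(_dc_replace(rec, annotation=ann))
        elif keep_unmatched:
            out.append(_dc_replace(rec, annotation=None))
    return out
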