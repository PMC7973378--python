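"""Hexamer (k-mer) counting and promoter motif over-representation.

The statistic: for motif m, with k_fg foreground promoters containing m out
of K_fg foreground promoters, and n_bg genome promoters containing m out of
N_bg genome promoters, the enrichment fraction is

    (k_fg / K_fg) / (n_bg / N_bg)

i.e. the motif's relative frequency in the selected cluster's promoters
over its genome-wide relative frequency. Significance is the upper-tail
hypergeometric probability P(X >= k_fg) of drawing that many motif-bearing
promoters in a sample of K_fg from a population of N_bg containing n_bg,
corrected across all observed motifs with the Benjamini-Hochberg step-up
procedure. The retention filter keeps motifs with enrichment >= 1.1 and
BH-adjusted q <= 0.05 (both defaults).

Two counting modes are available. ``presence`` (default) counts promoters
containing at least one occurrence; ``occurrence`` counts every overlapping
sliding window, with the denominators switching to total valid window
counts. Windows containing any non-ACGT character are skipped, and counting
is on the extracted promoter strand only — no reverse-complement merging,
so a motif and its reverse complement are scored independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._dna import decode_kmer, window_codes
from .promoters import PromoterSet

__all__ = [
    "MotifCountTable",
    "EnrichmentRecord",
    "count_motifs",
    "enrichment_fraction",
    "hypergeom_pvalue",
    "bh_adjust",
    "score_motifs",
    "filter_enriched",
    "records_to_frame",
    "frame_to_records",
]


@dataclass
class MotifCountTable:
    """Per-motif foreground/background counts with their denominators.

    ``counts`` is indexed by motif string with columns ``k_fg`` and
    ``n_bg``; every motif observed in the background (which includes the
    foreground) gets a row, so the multiple-testing family is stable even
    for motifs absent from the foreground.
    """

    counts: pd.DataFrame
    K_fg: int
    N_bg: int
    k: int = 6
    mode: str = "presence"


def count_motifs(
    promoters: PromoterSet | Mapping[str, str],
    foreground: Iterable[str],
    k: int = 6,
    mode: str = "presence",
) -> MotifCountTable:
    """Count k-mers in all promoters (background) and the foreground subset.

    ``promoters`` maps gene id to sequence (a :class:`PromoterSet` works);
    ``foreground`` lists gene ids that must all be present. In presence
    mode the denominators are promoter counts; in occurrence mode they are
    total valid sliding-window counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("presence", "occurrence"):
        raise ValueError(f"mode must be 'presence' or 'occurrence', got {mode!r}")
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else dict(promoters)
    fg = list(dict.fromkeys(foreground))
    missing = [g for g in fg if g not in seqs]
    if missing:
        raise KeyError(f"foreground gene(s) absent from promoter set: {missing[:5]}")
    fg_set = set(fg)

    size = 4 ** k
    bg_counts = np.zeros(size, dtype=np.int64)
    fg_counts = np.zeros(size, dtype=np.int64)
    bg_windows = 0
    fg_windows = 0
    for gid, seq in seqs.items():
        codes = window_codes(seq, k)
        if mode == "presence":
            u = np.unique(codes)
            bg_counts[u] += 1
            if gid in fg_set:
                fg_counts[u] += 1
        else:
            c = np.bincount(codes, minlength=size)
            bg_counts += c
            bg_windows += codes.size
            if gid in fg_set:
                fg_counts += c
                fg_windows += codes.size
    if mode == "presence":
        K_fg, N_bg = len(fg_set), len(seqs)
    else:
        K_fg, N_bg = fg_windows, bg_windows

    observed = np.nonzero(bg_counts)[0]
    counts = pd.DataFrame(
        {"k_fg": fg_counts[observed], "n_bg": bg_counts[observed]},
        index=pd.Index([decode_kmer(int(c), k) for c in observed], name="motif"),
    )
    return MotifCountTable(counts, K_fg=K_fg, N_bg=N_bg, k=k, mode=mode)


def enrichment_fraction(k_fg: int, K_fg: int, n_bg: int, N_bg: int) -> float:
    """(k_fg/K_fg) / (n_bg/N_bg): foreground over background relative frequency."""
    if K_fg <= 0 or N_bg <= 0:
        raise ValueError("denominators K_fg and N_bg must be positive")
    if n_bg <= 0:
        raise ValueError("motif absent from background (n_bg = 0) cannot be scored")
    if k_fg < 0:
        raise ValueError("k_fg must be non-negative")
    return (k_fg / K_fg) / (n_bg / N_bg)


def hypergeom_pvalue(k_fg: int, K_fg: int, n_bg: int, N_bg: int) -> float:
    """Upper-tail hypergeometric P(X >= k_fg).

    Population of N_bg promoters of which n_bg carry the motif; a sample of
    K_fg foreground promoters shows k_fg carriers. Evaluated through the
    survival function (log-space internally) for numerical safety; returns
    a value in (0, 1].
    """
    for name, v in (("k_fg", k_fg), ("K_fg", K_fg), ("n_bg", n_bg), ("N_bg", N_bg)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_bg > N_bg or K_fg > N_bg:
        raise ValueError("n_bg and K_fg cannot exceed the population size N_bg")
    if k_fg > min(K_fg, n_bg):
        raise ValueError(f"inconsistent counts: k_fg={k_fg} exceeds min(K_fg={K_fg}, n_bg={n_bg})")
    p = float(hypergeom.sf(k_fg - 1, N_bg, n_bg, K_fg))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class EnrichmentRecord:
    """One motif's full enrichment result."""

    motif: str
    k_fg: int
    K_fg: int
    n_bg: int
    N_bg: int
    enrichment: float
    p_raw: float
    q_bh: float
    passes: bool = False
    annotation: str | None = None


def score_motifs(table: MotifCountTable,
                 min_enrichment: float = 1.1,
                 alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Score every motif in a count table.

    Motifs absent from the foreground (k_fg = 0) get enrichment 0 and
    p = 1 rather than being dropped, keeping the BH family size equal to
    the number of motifs observed in the background. The hypergeometric
    model is exact for presence counts; for occurrence counts the same
    sampling model is applied to window counts.
    """
    k_fg = table.counts["k_fg"].to_numpy()
    n_bg = table.counts["n_bg"].to_numpy()
    enr = np.where(k_fg > 0, (k_fg / table.K_fg) / (n_bg / table.N_bg), 0.0)
    p = np.ones(len(k_fg))
    nz = k_fg > 0
    p[nz] = hypergeom.sf(k_fg[nz] - 1, table.N_bg, n_bg[nz], table.K_fg)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    q = np.asarray(bh_adjust(p)) if len(p) else np.empty(0)
    records = [
        EnrichmentRecord(motif=m, k_fg=int(kf), K_fg=table.K_fg, n_bg=int(nb),
                         N_bg=table.N_bg, enrichment=float(e), p_raw=float(pp),
                         q_bh=float(qq),
                         passes=bool(e >= min_enrichment and qq <= alpha))
        for m, kf, nb, e, pp, qq in zip(table.counts.index, k_fg, n_bg, enr, p, q)
    ]
    return records


def filter_enriched(records: list[EnrichmentRecord],
                    min_enrichment: float = 1.1,
                    alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Retain records with enrichment >= min_enrichment and q_bh <= alpha.

    Returns retained records sorted by enrichment descending, ties broken
    by raw p ascending; sets the ``passes`` flag on every input record.
    """
    kept = []
    for r in records:
        r.passes = r.enrichment >= min_enrichment and r.q_bh <= alpha
        if r.passes:
            kept.append(r)
    return sorted(kept, key=lambda r: (-r.enrichment, r.p_raw, r.motif))


_COLUMNS = ["motif", "k_fg", "K_fg", "n_bg", "N_bg", "enrichment", "p_raw", "q_bh",
            "passes", "annotation"]


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.motif, r.k_fg, r.K_fg, r.n_bg, r.N_bg, r.enrichment, r.p_raw, r.q_bh,
          r.passes, r.annotation if r.annotation is not None else ""]
         for r in records],
        columns=_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[EnrichmentRecord]:
    recs = []
    for row in df.itertuples(index=False):
        ann = getattr(row, "annotation", "")
        recs.append(EnrichmentRecord(
            motif=row.motif, k_fg=int(row.k_fg), K_fg=int(row.K_fg),
            n_bg=int(row.n_bg), N_bg=int(row.N_bg),
            enrichment=float(row.enrichment), p_raw=float(row.p_raw),
            q_bh=float(row.q_bh), passes=bool(row.passes),
            annotation=None if (isinstance(ann, float) and np.isnan(ann)) or ann == "" else str(ann)))
    return recs
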