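# Methods

## The model

`promoscan` asks whether short promoter motifs are over-represented in the
promoters of a selected gene set relative to all promoters in a genome.
The unit of counting is, by default, *presence*: a promoter either
contains at least one occurrence of a motif or it does not. With *k* of
*K* foreground promoters and *n* of *N* genome promoters carrying the
motif, the enrichment fraction E = (k/K)/(n/N) is the ratio of relative
frequencies, and the null model for significance is sampling without
replacement: the foreground is treated as a sample of K promoters from
the N genome promoters, so the number of carriers in the foreground is
hypergeometric and the reported p is the upper tail P(X ≥ k). Because the
foreground is a subset of the background, k ≤ n always holds and the
hypergeometric population is well defined.

An *occurrence* counting mode is also provided, in which every overlapping
k-mer window is counted and the denominators become total valid window
counts. The enrichment arithmetic is identical; the hypergeometric model
is then an approximation (windows within a promoter are not exchangeable
draws), which is the main reason presence mode is the default. Windows
containing any non-ACGT character are skipped in both modes. Counting is
strand-specific: a motif and its reverse complement are distinct
hypotheses, and no collapsing is done.

Multiple testing uses the Benjamini–Hochberg step-up procedure over *all*
motifs observed in the background — not only those clearing the effect
size threshold — because correcting after an effect-size filter would
misstate the FDR. Motifs absent from the foreground are kept in the family
with E = 0 and p = 1 so the family size does not depend on the foreground.
The retention filter (E ≥ 1.1 and q ≤ 0.05 by default) is applied after
adjustment, and retained motifs are reported sorted by E descending with
raw p breaking ties.

## Trend clustering

Genes are clustered on their replicate-mean expression per
(genotype, treatment) cell — four values per gene in a 2×2 design —
after row z-scoring, using Euclidean distance and complete linkage
(scipy's implementation, which is deterministic for a given input).
Z-scoring is what makes the clustering group by *trend shape*; complete
linkage on raw FPKM would group by expression magnitude instead. A
consequence worth knowing: genes with no treatment or genotype effect have
profiles that are pure noise, and z-scoring inflates that noise to unit
variance, so "flat" genes do not form a tight cluster. Cluster labels are
therefore decided per cluster from mean fold changes, not from proximity
to a flat reference.

Each cluster's label comes from its mean per-genotype
log2((flooded + c)/(control + c)) with pseudocount c = 1 FPKM (avoids
division by zero; FPKM-scale standard practice): *up_A_enhanced* requires
a positive mean fold change in the reference genotype that strictly
exceeds the other genotype's; *down_A_enhanced* is the strict mirror;
everything else is *other*. Strict inequalities mean exactly tied
responses fall into *other*. The cluster count is a required parameter
(default 8): the labeling is applied per cluster, so a generous cluster
count mainly splits *other* finer. The reference genotype defaults to the
alphabetically first label in the design.

## Promoter extraction

Promoters are the up-to-L bases (default L = 1000) immediately 5′ of the
gene-level TSS, excluding the TSS base: [TSS−L, TSS−1] on the forward
strand for + genes, and the reverse complement of [TSS+1, TSS+L] for −
genes, in 1-based inclusive coordinates (internally 0-based half-open;
GFF3 converts at the boundary). Where a GFF3 gene has mRNA children, the
TSS is the 5′-most mRNA start on the gene's strand; otherwise the gene's
own 5′ end. Windows truncated by a contig edge are retained at their
actual length rather than discarded — discarding would silently shrink
the background N — and a gene whose window is empty is skipped with a
warning. No trimming against neighbouring genes is attempted. Lowercase
(soft-masked) input is uppercased; Ns survive extraction and are excluded
from counting at the window level.

## Cis-element annotation

The bundled element table is a curated, PLACE-style snapshot, not a live
database query, for reproducibility and offline operation; it is
user-replaceable. A motif matches a row if the row's IUPAC pattern occurs
position-wise within the motif, or (for patterns longer than the query)
the motif occurs within the pattern; matching is on the counted strand,
with reverse-complement matching available as an option. The snapshot
mixes two row types, distinguished by the `source` column:
consensus-core rows (short cores such as ACGT, CACT, GTAC, CAAT) and
curated hexamer rows that record established element-to-hexamer
assignments not derivable from the cores under any substring rule. By
default only positively matching motifs are reported; annotation never
alters the statistics columns.

## Synthetic data: what it emulates and what it does not

The generator emulates the three inputs the pipeline consumes. Genomes
are i.i.d. base sequences at a configurable GC fraction (default 0.38,
a typical plant gene-space value) with genes placed on alternating
strands between intergenic spacers longer than the promoter window, so
promoters are full-length and never overlap neighbouring genes by
construction. Motif planting overwrites exactly k bases at a uniform
offset in each selected promoter, with per-promoter presence
probabilities for foreground and background sets; the ground-truth log
records planted copies only, and chance occurrences elsewhere are
possible — which is why tests count presence, monotone under extra
copies. Expression matrices follow the study design this package targets:
2 genotypes × 2 treatments × 3 replicates, a baseline of 20 FPKM, planted
trend groups at log2 fold changes of 2 (reference genotype) and 1 (other
genotype) with the repressed group mirrored, and multiplicative
log-normal noise (σ = 0.1 on the natural-log scale by default). FPKM-level
log-normal noise was chosen over count-level negative-binomial noise
because the analysis consumes FPKM, not raw counts.

What the generator does *not* emulate: real promoter base composition
(dinucleotide structure, TATA/CpG-like heterogeneity), correlated motif
co-occurrence, isoform-level TSS variation, library-size artefacts, or
count-level overdispersion. Passing the planted-recovery tests therefore
demonstrates the statistics and bookkeeping are correct, not that any
particular biological motif list would be recovered from real data.

## Numerical choices

The hypergeometric tail is evaluated through scipy's survival function
(log-space internally) and clipped into (0, 1]; it agrees with exact
integer-arithmetic summation to better than 1e-12 relative error over the
exhaustive N ≤ 30 grid, and the test suite keeps that dual route. The BH
adjustment is statsmodels' `fdr_bh`, checked against a from-definition
step-up oracle on exhaustive permutations. Enrichment fractions are
computed and reported in full double precision. k-mer counting encodes
windows in base-4 integer codes and is verified against a brute-force
string scan. Row z-scoring maps constant rows to zero vectors rather than
NaN. Agglomeration tie-breaking is delegated to scipy's deterministic
linkage; permutation invariance of memberships is guaranteed (and tested)
for inputs without exact distance ties.

## Problem sizes

The test suite and the verification fixtures run at desk scale by design:
the bundled count-table fixture carries the published foreground and
background counts directly (K of 849 and 631 against N = 34,417), so the
enrichment arithmetic is checked at full scale, while the stochastic
recovery checks use 2,200 synthetic promoters of 1,000 bp (200
foreground), a 300-gene expression matrix, and 20-seed null calibration
batches — sizes at which every property being asserted is already
informative and the whole suite runs in well under a minute.

## Known limitations

Presence-mode counting discards copy-number information within a
promoter; occurrence mode keeps it but weakens the sampling model. The
enrichment fraction has no variance stabilisation, so motifs with tiny
background counts can show large but noisy E — the hypergeometric q is
what guards against over-reading them. Cluster labeling uses strict
inequalities on cluster means and therefore has no effect-size floor: a
cluster with a negligible but consistently larger response in the
reference genotype is still labeled. The bundled cis-element table is a
small snapshot; serious annotation work should supply a fuller table via
`--elements`.
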