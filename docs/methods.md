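# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data results do and do not show about real
genomes.

## Coordinates and sequence conventions

All intervals are 0-based half-open internally; GenBank's 1-based inclusive
coordinates are converted at the parsing boundary (`a..b` ↔ `(a−1, b)`, a
bijection).  `complement()` features map to strand `−`; `join()` parts are
kept in ascending order and concatenated before reverse complementing, so a
minus-strand CDS always reads 5′→3′ in coding direction.  Sequences are
stored upper-case; the ambiguity base N is legal in nucleotide records but
is excluded from both numerator and denominator of every GC fraction
(counting N as A/T would bias estimates under ambiguity).  Translation uses
the standard bacterial code; GTG/TTG starts are read as methionine only
when the `actinobacterial_starts` flag is set, since those starts are
common in Actinobacteria but not universal.  Partial CDS (no in-frame stop,
or length not a multiple of 3) are flagged and excluded from codon-level
statistics rather than rejected, because annotation at contig edges is
routinely truncated.

## Composition statistics

* **GC content** is (#G+#C)/(#A+#C+#G+#T).  Windowed profiles emit one
  point per complete window, indexed by the window *center*
  (start + window/2); the trailing partial window is dropped.  Centering
  gives symmetric plots and a deterministic point count
  ⌊(L−w)/s⌋ + 1.
* **GC1/GC2/GC3** count all codons including the start.  The terminal stop
  codon is excluded by default: stop codons are under their own selection
  regime and are censused separately, so leaving them in would leak the
  stop-codon signal into GC3.  Both conventions are available
  (`drop_terminal_stop`).  With the stop excluded, the identity
  mean(GC1, GC2, GC3) = GC(cds) holds exactly and is property-tested.
* **Outlier report.**  z₃ and z₁₂ are standard scores (population sd, so
  mean 0/sd 1 exactly) of GC3 and mean(GC1, GC2) across a contig's genes;
  a gene is flagged when z₃ ≥ z\* and z₁₂ ≤ −z\* (default z\* = 2).  This
  scoring is a formalization defined by this package — a convenient,
  contig-internal way to state "third position saturated, constrained
  positions depressed" — not a published statistic.  It needs ≥ 3 genes and
  assumes the contig's native genes are roughly homogeneous; on contigs
  with strong gene-to-gene heterogeneity the z-scores lose power.
* **Protein mass** is the sum of IUPAC average residue masses plus one
  water (18.015 Da), reported in kD; Dps-family subunits run ~16–24 kD.

## Stop-codon census and trend

The stop codon of a gene is the last in-frame codon of its strand-aware
CDS.  Census fractions are over complete CDS only; partial counts are
reported separately, never imputed.  Multi-replicon genomes use
length-weighted genomic GC.  The usage-vs-GC trend is summarized with
Spearman's ρ (the relationship is monotone but visibly nonlinear;
Pearson is available behind a flag).  In the tie-free case ρ is computed
with the exact integer formula 1 − 6Σd²/(n(n²−1)) so perfectly monotone
data give exactly ±1; a constant response (a codon never used) yields NaN.
Correlation requires ≥ 4 genomes and errors on constant GC
("degenerate predictor").

## Distance phylogenetics

* **Alignment**: global Needleman–Wunsch/Gotoh with BLOSUM62, gap open 10,
  gap extend 0.5 (a gap run of length L costs 10 + 0.5 L) — the classic
  ClustalX-style protein settings, all configurable.  The observed distance
  D is the mismatch fraction over columns with no gap in either row.
* **Correction**: Kimura's protein-distance approximation
  d = −ln(1 − D − D²/5), valid for D < 0.85.  Beyond the domain the call
  errors unless `fallback_raw` substitutes the uncorrected D; matrix
  construction and the bootstrap default to the fallback so one saturated
  pair cannot abort an analysis.
* **Neighbor joining** follows Saitou–Nei: join the pair minimizing
  Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with the standard
  branch-length and distance-reduction formulas.  Q ties are broken by the
  lexicographically smallest pair of cluster labels (each cluster keyed by
  its smallest leaf), making output deterministic.  Negative branch lengths
  are clamped to 0 with the deficit moved to the sibling edge, preserving
  the joined pair's path length.  NJ is consistent on additive matrices;
  exact recovery (topology and lengths to 1e−9) is property-tested against
  random trees.
* **Bootstrap** resamples alignment *columns* (not distances) with
  replacement, rebuilds the distance matrix and NJ tree per replicate, and
  reports per-bipartition support as a percentage.  Resampling depends only
  on the seed; taxa are processed in sorted-label order, so supports are
  invariant under input taxon order.  Supports are attached to internal
  nodes as integer percentages.
* **Rooting** places the root at the midpoint of the outgroup's pendant
  edge.  Supports annotate bipartitions, which re-rooting does not change,
  so they are carried across unchanged.

## Synteny

Neighborhoods are k = 8 genes per side of the anchor (gene ranks, not bp,
because intergenic spans vary wildly across genomes) and are mirrored when
the anchor lies on the minus strand so all anchors read left-to-right.
Orientation vocabulary, defined here because usage in the literature is
loose: for two non-overlapping genes with the smaller-start gene upstream,
same strand = *co-directional*; `+ −` = *face-to-face* (convergent);
`− +` = *back-to-back* (divergent).  Ortholog pairs are reciprocal best
hits by global alignment score, accepted when the score reaches 30% of the
self-score of the shorter protein — a self-contained stand-in for a
database search that behaves well at neighborhood scale (a dozen proteins
per genome).  Groups are the transitive closure of pairs, merging
highest-scoring edges first and refusing merges that would place two genes
of one genome in the same group; groups spanning ≥ 2 genomes are
"conserved".  This deliberately does not handle paralog families or
genome-scale rearrangement.

## Synthetic data: what it emulates, and what not

`gen_genome` samples codon positions 1–2 and position 3 independently
(Bernoulli GC at `target_gc12` / `target_gc3`, uniform within {G,C} or
{A,T}), rejection-sampling away stop codons, with ATG starts, weighted
stops, random strands and Poisson-length intergenic spacers.  This is the
minimal model that decouples GC12 from GC3 — the degrees of freedom the
amelioration analysis reads — and it makes targets verifiable: realized
per-gene GC1/GC2/GC3 are recorded in a truth record recomputed from the
emitted sequence.  It has **no amino-acid realism** (no codon-usage table,
no gene-level functional constraint), no promoters/RBS, and no overlapping
genes.  Defaults (30 genes of ~200 codons, GC3 0.90, GC12 0.58, TGA-heavy
stops, ~120 bp spacers) emulate a high-GC actinobacterial replicon;
`aah_like_contig` instantiates the study design — 26 host genes at contig
GC ≈ 0.69 plus one planted gene with GC3 ≈ 0.94, GC12 ≈ 0.54, a ~17 kD
product and the contig's only TAA stop.

`gen_genome_panel` spaces genome GC evenly across a range and moves stop
weights linearly with relative GC (TAA 0.85→0, TGA 0→0.85, TAG flat 0.15
at full trend strength; uniform at strength 0).  `simulate_protein_family`
evolves a uniform random root sequence along a random-join topology under
a 20-state Jukes–Cantor-like model: per site, Poisson(rate × branch length)
events, each replacing the residue uniformly among the other 19, giving
the closed-form expected mismatch 19/20·(1 − e^(−20/19·rt)) used as a
simulator check.  There are **no indels**, so the leaves are their own true
alignment and bootstrap operates on the exact columns.  Branch lengths are
`min_branch_length + Exponential(mean − min)` with a default floor of
0.02: a pure exponential puts appreciable mass on internal edges too short
to resolve at the simulated sequence lengths, which measures edge
identifiability rather than the estimator.  Consequently the
parameter-recovery results say: *given resolvable edges and a correct
alignment*, the distance/NJ chain recovers the generating topology ≥ 90%
of the time at 8 taxa × 1000 residues — they do not certify performance on
real alignments with indels, rate heterogeneity or alignment error.

## Problem sizes and determinism

Every generator is a pure function of spec + seed (byte-identical reruns);
seeds are explicit arguments, never global state.  The validation suite
uses 200 additive matrices (4–12 taxa) for NJ consistency, 100 brute-force
comparisons each for alignment and composition oracles, 50 simulated
families for topology recovery, 200 bootstrap replicates on a planted
two-clade alignment, 20 thirty-genome panels (60 genes each) for the
stop-codon trend with a 500-permutation null, and 10 planted-insert
contigs for foreign-gene recovery — sizes at which the Monte-Carlo
thresholds above are stable across seeds while the whole suite runs in
well under a minute.
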