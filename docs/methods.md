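# Methods

## Pair scoring

The unit of similarity is the shared substring. For a target token sequence
S of length n and a reference R, every start position i of S contributes
l_i, the length (in tokens) of the longest substring of S beginning at i
that occurs contiguously anywhere in R; ARS(S, R) is the mean of the l_i.
The score is asymmetric (R may contain S without the converse), so the pair
score averages the two directions. Units are tokens: nucleotides for
promoter windows, codons for CDS windows. Two consequences worth keeping in
mind: a sequence scored against itself gives exactly (n + 1) / 2, and the
score grows with any shared repetitive content, not only with homology.

Each l_i is found by binary search in a suffix array built once per
sequence: the query suffix is located among the reference's sorted suffixes
and the answer is the longest common prefix with the insertion point's
neighbours. This is exact — the test suite checks bit-equality against an
all-substrings brute-force scan over random nucleotide and codon sequences.

Ambiguity codes (N and friends) match nothing, not even an identical token;
this is implemented by truncating every query suffix at its first ambiguous
token, which is equivalent because an ACGT-only token can only equal another
ACGT-only token. Runs of N therefore cannot manufacture similarity.

### Regions and aggregation

Promoters use the window immediately upstream of the start codon (default
100 nt, tokenized per nucleotide); CDS uses the first 498 nt (166 codons).
498 rather than a round 500 keeps the window codon-aligned; a 249-nt setting
suits compact prokaryotic genomes. Region scores combine by a weighted
arithmetic mean with weights equal to the window lengths in nucleotides
(100 : 498), i.e. coding sequence carries about five times the weight.
Genes shorter than the CDS window are scored on their full frame-trimmed
CDS; genes with no promoter record fall back to the CDS score alone.

## Network construction

Rows of the score matrix are compared with Spearman rank correlation — the
relationship between two genes' score profiles is expected to be monotone,
not linear. Before ranking, the two self-score columns of the pair are
removed from both rows: self-similarity values are scale outliers that would
inflate every correlation. A constant row after removal gets rho = 0 with a
warning rather than NaN, so downstream thresholding stays total.

Edges keep pairs with rho at or above the cutoff (default 0.6). The
alternative `target_density` mode picks the largest cutoff reaching a target
edge density, the device used to compare networks of different organisms at
equal density. Components are then connected by scanning excluded pairs in
descending rho (ties broken by the lexicographic gene-id pair, for
reproducibility) and adding an edge whenever the endpoints lie in different
union–find components — Kruskal's algorithm run over components, adding
exactly (components − 1) edges, each flagged `connectivity-added` so the
thresholded graph is recoverable.

The 2D embedding is networkx's weighted Fruchterman–Reingold layout with a
tight convergence threshold (1e-8, up to 500 iterations) and a *uniform*
min–max rescaling into the unit square — uniform so the embedding's geometry
(e.g. the symmetry of an equal-weight triangle) is not distorted by
per-axis scaling.

## Protein-preserving randomization (ppCSN)

All occurrences of each synonymous codon class are pooled across the whole
gene set and permuted uniformly, then written back to their original (gene,
position) slots; promoters are permuted per sequence at nucleotide level.
Invariants: per-gene protein sequence, per-gene length, global codon
multiset, per-promoter nucleotide multiset and global GC are all exactly
conserved. Per-gene GC is *not* conserved (the shuffle is global by design;
a per-gene-only variant exists behind a flag for sensitivity analysis).
Stop codons form their own class; with windowed CDS prefixes they rarely
occur. The control network is built at the same cutoff and then forced to
the exact edge count of the paired network: deficits are filled by the
highest-correlation excluded pairs (flagged `count-matched`); surpluses are
drained by removing the lightest thresholded edges — never connectivity
edges — reconnecting whenever a removal splits the graph, and freezing any
edge whose removal the reconnection immediately undoes.

## Evaluation battery

- Degree-distribution fit: correlation between log10(degree) and
  log10(frequency) over the distinct observed degrees (no binning). With
  fewer than two distinct degrees the statistic is undefined.
- Degree–expression: Spearman and Pearson over the genes shared between the
  network and the abundance table.
- CAI: relative adaptiveness w_c = count(c) / max count in c's synonymous
  class, counts taken over the *whole* windowed gene set with a 0.5
  pseudo-count for unobserved codons; a gene's CAI is the geometric mean of
  w over its codons, skipping the single-codon classes (Met, Trp). The
  combined expression regressor is OLS of log abundance on (CAI, degree),
  summarized by the Spearman correlation of fitted values with abundance.
- Interaction recovery: sensitivity is the fraction of reference pairs (both
  endpoints in the common gene set) present as edges; the ROC treats rho as
  a score over all pairs among reference-covered genes and sweeps every
  distinct value; the trapezoid AUC equals the tie-averaged Mann–Whitney
  statistic (asserted in tests).
- Neighborhood enrichment (simplified SAFE): a node's neighborhood is its
  radius-1 hop ball (itself included) or, in layout mode, the disc of radius
  0.05 in unit-square coordinates. Each term with at least one hit is tested
  with the exact hypergeometric upper tail against the whole-graph
  background; BH-FDR is applied across all (node, term) tests, alpha 0.05.
  Enriched (node, term) pairs become annotation predictions; the success
  rate is the fraction already known (a precision-like quantity), the rest
  are novel predictions.

## Synthetic study design

The generator emulates the single regularity the method rests on:
functionally related genes share sub-sequences. Default conditions: 5
families × 20 genes; CDS length 498 nt (matching the scoring window, so all
planted signal is visible to the scorer) and 100-nt promoters; per family 6
codon motifs of 8 codons and 6 promoter motifs of 10 nt, each carried by
90% of members, planted codon-aligned (CDS) or nt-aligned (promoter) by
overwriting a random window, so lengths stay fixed. Background codon usage
is drawn once per synonymous class from a Dirichlet with concentration 0.5 —
a strongly biased usage, as real genomes show; stops are excluded so frames
are clean. Six motifs per family (rather than fewer) is a deliberate choice:
a gene's motif load must have enough dynamic range to couple to downstream
statistics, because rank correlation is scale-invariant and load reaches
node degree only through the *reliability* of family recognition, not
through raw score magnitude.

Expression is exp(0.6 · load + N(0, 0.4)) where load is the number of
motifs carried — a monotone function of motif load with lognormal noise.
The induced degree–expression association is weak and noisy by nature (the
method's real-data counterpart is also weak); at the default preset it is
positive and significant, but at 100 genes this statistic has wide sampling
variability across generator seeds. Annotations are the family labels;
the reference interaction network is the union of within-family cliques
with 10% of edges rewired to random pairs as noise.

What the generator does *not* emulate: indels and local rearrangement,
phylogenetic correlation structure, overlapping/partial family membership,
length variation, and any realistic relationship between promoter content
and expression machinery. Passing the planted-structure tests shows the
pipeline recovers block structure carried by shared substrings at realistic
codon bias — not that it reproduces any particular organism's numbers.

## Numerical and degenerate-input choices

- Suffix arrays are 0-based internally; token comparison is whole-token
  lexicographic (codons compare as 3-char strings).
- Score and correlation matrices are dense float64; TSV export uses %.10g.
- Fewer than 3 genes is a hard error (row correlation needs 3 columns).
- `match_edge_count` refuses targets below n − 1 (cannot stay connected).
- Hypergeometric tails use scipy's `hypergeom.sf(k−1, N, K, n)`; tests pin
  them to exact big-integer binomial sums at 1e-12.
- All stochastic steps take explicit integer seeds; two runs with the same
  seeds produce byte-identical exports (asserted in tests).

## Problem sizes

The default study (100 genes, 4,950 pairs, two networks) runs in ~20 s on
one CPU; unit tests use 3×5-gene genomes and ≤10-node graphs. Scores scale
quadratically in gene count and roughly linearly in window length, so
genome-scale runs (thousands of genes) are feasible but benefit from
splitting the pair loop across processes — pair scores are independent by
construction.

## Known limitations

- The scorer counts *any* shared substring: repeats, low-complexity tracts
  and compositional bias all raise scores. The ppCSN control exists
  precisely to calibrate this.
- The enrichment procedure is a deliberately simplified SAFE: per-node
  neighborhoods, hypergeometric tail, BH-FDR — no region merging, no
  multi-scale radii.
- Retained edges are not given p-values; the correlation itself is the edge
  weight, and density matching is the supported way to compare networks.
- Promoter extraction from genomic coordinates (GFF) is out of scope; the
  promoter FASTA must contain pre-extracted upstream sequence.
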