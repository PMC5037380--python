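# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `wellcount`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A bead-barcoded 3′-end library encodes, for every sequenced cDNA fragment,
a 12-nt cell barcode and an 8-nt UMI on read 1 and the fragment itself on
read 2 (26 and 66 sequencing cycles respectively; both lengths and the
barcode/UMI layout are configurable via a compact spec such as `12C8M`).
The central counting object is the **address** — the (gene, UMI, cell
barcode) triple of a retained read. Absent amplification and sequencing
errors, distinct addresses are distinct captured molecules.

## Read processing

* **Poly(A) clipping.** The clipper removes the longest 3′-terminal suffix
  that starts with an A, is at least 6 nt long, and contains at most one
  non-A per 10 bases of suffix — the mismatch allowance keeps a tail with an
  isolated sequencing error clippable. The operation is idempotent (proved
  by the floor-sum inequality `⌊a⌋+⌊b⌋ ≤ ⌊a+b⌋` and asserted as a property
  test). Fragments shorter than 25 nt after clipping are discarded;
  the boundary is inclusive (a 25-nt fragment is kept).
* **No barcode correction at extraction.** Split-pool bead barcodes have no
  whitelist; erroneous barcodes are handled implicitly by cell calling
  (they carry few molecules). Barcodes containing N are excluded before
  cell calling since they cannot be genuine bead sequences.

## Alignment and retention

A read is retained iff (i) its best alignments land on transcripts of
exactly one gene (gene-level uniqueness: multiple isoforms of one gene do
not discard a read; ties at maximal score across genes do — purity over
yield), (ii) the alignment is to the transcript's forward strand (3′-end
libraries sequence the mRNA sense strand on read 2), and (iii) the
alignment score is ≥ 0.85 × fragment length, inclusive. With external SAM
input the AS tag supplies the score, falling back to
`fragment_length − NM`; records with neither are discarded (`no_score`).
Secondary records are grouped with their primary by query name before the
uniqueness test.

The built-in aligner (exact 15-mer seeding, ungapped extension, score =
matching bases, both orientations, k-mers occurring > 64 times masked as
low-complexity) exists to make the package self-contained and testable; it
is not a substitute for a production aligner on real data, which has
introns, isoform overlap, and indels.

## UMI collapse

Within each (cell barcode, gene) combination, addresses are visited in
ascending (read count, UMI) order; each merges into its highest-coverage
neighbour at **Hamming** distance 1 provided that neighbour's *current*
read count is strictly greater (a tie is not a higher-coverage address and
is left alone; target ties break to the lexicographically smallest UMI).
Read counts accumulate, so a survivor that absorbs error UMIs can
subsequently absorb neighbours it previously tied with — but only
neighbours visited after it; the pass is single, not iterated to a fixed
point, matching the rule "merge this address into a higher-coverage
neighbour if one exists" applied once per address. Hamming rather than
Levenshtein distance because UMI length is fixed by the read layout — an
indel would change the tag length. Total read counts are conserved and the
number of addresses never grows; the whole procedure is checked against an
independent brute-force pairwise implementation on random groups.

An inherent ambiguity: when two true molecules collide on the same UMI
(one address with doubled coverage) and a third true molecule sits at
distance 1, the rule merges the third molecule away. The end-to-end oracle
therefore compares the pipeline's *raw* address table to the simulated
truth exactly (read counts included), and the final matrix to the truth
table passed through the same collapse rule, whose own correctness has the
brute-force oracle.

## Cell calling

Barcodes are ranked by descending molecule count. On the log10(count) vs
log10(rank) curve, the point farthest above the chord joining the curve's
endpoints locates the scale of the break between the cell plateau and the
ambient tail; the threshold is then refined to the largest multiplicative
drop between consecutive barcodes in a window around that point (from half
the chord-knee rank to four times it). The refinement matters because
Poisson dips within the cell plateau can pull the raw chord maximum a few
ranks inside the plateau. All barcodes at or above the knee count are
selected. Degenerate distributions (all counts equal) raise an error
directing the user to `--expected-cells`, the override for runs where
imaging gives the number of cell-bead pairs.

## Mixed-species QC

Purity uses only molecules of genes with an unambiguous species label.
A barcode is a multiplet iff purity < 0.90 strictly (exactly 90% is not a
multiplet). The observed multiplet fraction counts only cross-species
doublets; dividing by `2·p_h·p_m` (estimated from the singlet calls) gives
the corrected total doublet-rate estimate reported alongside. Same-species
doublets remain undetectable by this statistic — a limitation of the
barnyard design itself, not of the implementation.

## Saturation

Reads are expanded from pre-collapse address read counts and subsampled
without replacement (multivariate hypergeometric over addresses). By
default each depth is an independent draw from the common seed; a nested
mode (chained subsampling, so read sets are strictly nested across depths)
is available via a flag. Addresses are rebuilt and the UMI collapse
re-applied at every depth. Re-collapsing is not formally monotone in the
read subset (a tie can flip into a merge as counts grow) but the effect is
a handful of molecules against depth increments thousands strong; observed
curves are non-decreasing, and the tests assert that on fixed-seed
realizations. Pooled totals and per-cell means are both reported since
either convention is found in practice.

## Cell-cycle classification

Phase scores are the mean log-normalized expression — `log(1 + 10⁴·f)` of
per-cell molecule fractions `f` — over each phase's gene set, z-scored
across cells per phase (population SD; a zero-variance column is defined as
all-zero). This is the plain one-pass score; the iterative refinement that
re-selects correlated genes within each set is deliberately not applied.
The ten reference patterns are the eight on/off combinations along the
cycle (G1/S; G1/S+S; S; S+G2; G2; G2+G2/M; G2/M; G2/M+M/G1) plus all-on and
all-off, encoded +1/−1 (0/1 encoding gives the identical Pearson argmax).
All-on/all-off have zero variance, so correlation with them is undefined;
they are assigned by rule first — all scores strictly positive or strictly
negative respectively. Otherwise the cell takes the cycle pattern with
maximal Pearson correlation, ties to the lower index. Within a cycle class,
cells are ordered by `corr(succeeding) − corr(preceding)` on the circular
pattern sequence, which increases monotonically along transitional states.

## Heterogeneity analyses

* **Normalization**: molecule counts divided by the cell's total molecules;
  log transforms use `log(1 + scale·x)` with scale 10⁴ (configurable).
* **HVG selection**: genes detected in ≥ 5 cells enter the analysis; 50
  evenly spaced bins partition the range of log10 mean expression; within
  each bin the z-score of log10 CV (sample CV, ddof = 1) is computed
  against the bin's members (population SD). Logs stabilize the heavy right
  tail of the CV distribution. Selected genes need z > 3, detection in
  ≥ 10% of cells and ≥ 5 cells. Bins with fewer than two eligible members
  give z = 0 — with one member there is no dispersion baseline. A top-up
  helper (`hvg_gene_list`) pads the list to a minimum size with the
  highest-dispersion eligible genes for small datasets where few genes
  clear the threshold.
* **Clustering**: the rows of the cell × cell Pearson correlation matrix
  over log expression of the HVGs are the t-SNE feature vectors
  (perplexity 30 default; a `1 − r` precomputed-distance mode is exposed);
  DBSCAN with Euclidean metric labels the 2-D embedding, eps defaulting to
  1.5× the elbow of the ascending sorted k-NN distance curve
  (k = min_samples). Seeds are explicit everywhere; identical seeds give
  identical embeddings and labels. Per-cluster median molecule counts are
  reported so coverage-driven separation is visible at a glance.
* **Marker-set score**: `S_i = (n_subtype,i / N_subtype) / n_genes,i`, with
  detection = count ≥ 1 and `N_subtype` the set's genes detected anywhere in
  the dataset. S is monotone in the cell's detected subtype genes,
  normalized by the set's detectable size, and penalized by the cell's
  overall detection breadth (doubling `n_genes,i` halves S); S = 0 when no
  subtype gene is detected.
* **Enrichment**: population = clustered cells (noise excluded by default;
  a flag includes it); successes = scores strictly above the population
  median (ties at the median do not count); p = upper-tail hypergeometric
  `P(X ≥ overlap)`. Bonferroni-corrected values are emitted alongside raw
  p when several clusters × gene sets are tested from the CLI.

## The simulator and what passing tests do (and do not) show

The synthetic experiment emulates the structure of a two-species microwell
run: random 12-mer bead barcodes drawn without replacement; per-species
lognormal gene-expression weights; per-cell molecule counts from a
configurable distribution (default Poisson, mean 500); doublet wells at a
configurable rate whose second cell's species follows the mixture
proportions; empty-bead barcodes capturing Poisson ambient molecules
(default mean 2) from the pooled cellular profile; uniform random 8-mer
UMIs; fragments starting uniformly in the final 150 nt of the gene body;
substitution errors at a per-base rate. Read 1 is barcode + UMI padded with
A; read 2 may run into the poly(A) tail and is padded with A past the
transcript end. A ground-truth SAM (sense strand, true positions, AS/NM
tags) accompanies the FASTQ for exercising the external-alignment path.

Toy transcript bodies contain no A-run longer than 3 nt, and fragment
starts keep a minimum gene-body overlap derived from the clipper's
mismatch allowance (44 nt for 66-cycle reads). Together these guarantee
that an error-free fragment always survives the 25-nt post-clip filter and
maps uniquely — which is what makes the exact end-to-end oracle possible.

Features of real data deliberately absent: indels and realistic error
profiles, PCR amplification bias, bead-synthesis barcode errors, ambient
RNA inside cell-containing wells, intronic/antisense transcription, isoform
structure. Passing the end-to-end oracle therefore certifies the
*bookkeeping* — parsing, clipping, filtering, counting, collapsing, calling
— not alignment accuracy on real genomes or robustness to real noise.

Downstream generative models: cycling cells sit on one of the eight cycle
patterns with a pseudotime offset in (−0.4, 0.4) interpolating toward the
flanking patterns, phase genes elevated by a lognormal fold (median 4),
10,000 molecules/cell — a depth typical of well-covered runs; the
two-population clustering model plants disjoint 50-gene modules at 8-fold
elevation over a wide-dynamic-range background (lognormal σ = 1.5, chosen
so module genes scatter across mean-expression bins rather than crowding
the sparse top bins); the HVG model plants 20 bimodal genes (10-fold, on in
30% of cells) with base rates centred slightly below background so their
means land where bins are well populated — where real markers live.

## Numerical conventions and degenerate inputs

* Score/length/purity boundaries are all inclusive-as-documented: kept at
  exactly 0.85 × length, kept at exactly 25 nt, not-multiplet at exactly
  0.90 purity.
* Zero-variance cells get zero correlation to all others (unit diagonal
  kept); zero-variance phase-score columns are all-zero; constant score
  vectors classify to pattern 1 with correlation 0.
* Empty cells (zero molecules) are an error in normalization and phase
  scoring rather than silently dropped.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs or arguments; equal seeds reproduce byte-identical FASTQ/SAM and
  identical analysis outputs.

## Problem sizes

The validation study (`scripts/acceptance.py`) uses 200 cells × ~500
molecules × 3 reads (~300k read pairs) for the end-to-end oracle, 1,000
cells per planted multiplet rate, 5,100 barcodes for cell calling, 500
cells for cell-cycle recovery, 400 cells / 2,020 genes for HVG and
clustering, 1,000 random groups for the collapse oracle and 20
configurations × 100,000 permutation draws for the enrichment check —
sizes at which every statistical property is stable across seeds while the
whole study completes in well under a minute on one CPU.
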