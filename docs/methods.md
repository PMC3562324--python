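# Methods

## Problem setting

Genomes of plant-biomass-degrading fungi carry a few hundred
carbohydrate-active enzyme (CAZyme) genes, of which on the order of a
hundred act directly on the plant cell wall (cellulases, hemicellulases,
β-glucosidases, pectinases, expansin-like proteins, tannases, cellobiose
dehydrogenases). Two architectural questions recur in genome reports: are
these genes clustered more tightly than chance placement allows, and do the
dense neighbourhoods sit near chromosome ends? `cazyclust` answers both
from three inputs — a GFF3 annotation, scaffold FASTA, and a gene-category
TSV — and makes no attempt to produce the category labels themselves
(domain annotation is a separate, upstream task).

All coordinates are 0-based half-open internally; GFF3 (1-based closed) and
BED are converted at the I/O boundary. Genes are ranked per scaffold by
(start, end, gene_id) — the tie-break for coincident starts is a package
convention, since no standard exists for overlapping genes.

## Cluster enrichment model

A *candidate cluster* is an ordinal interval `[i, j]` of consecutive genes
on one scaffold whose first and last genes are label-positive. Every such
interval with at most `max_window_genes` genes (default 50) is enumerated
and scored with the hypergeometric upper tail

P(X ≥ k), X ~ Hypergeom(N, K, n),

where `N` is the total gene count of the genome, `K` the genome-wide count
of labelled genes, `n = j − i + 1` the window size and `k` the labelled
genes inside the window. Modelling choices:

- **Genome-wide background.** `N` and `K` are genome totals, not
  per-scaffold, because the question is enrichment against the whole-genome
  census.
- **Gene-count windows.** Windows are measured in genes, which makes the
  "draws" of the hypergeometric model well-defined; intergenic distances do
  not enter.
- **Raw threshold.** Significance is `P ≤ alpha` with `alpha = 0.001`,
  inclusive, with no multiple-testing correction by default. Overlapping
  windows are heavily dependent, so Bonferroni across all candidates is
  badly conservative; it is exposed as an option (`--bonferroni`) but off.
- **Window cap.** `max_window_genes = 50` bounds the enumeration (quadratic
  in the labelled genes per scaffold otherwise). Enzyme-dense regions of
  interest contain tens of genes, not hundreds; the cap is configurable.

The tail is computed by summing log-space terms built from log-factorials
(`scipy.special.gammaln`, combined with `logsumexp`), giving relative error
below 1e−10 against exact rational arithmetic over the tested range and
finite log-scale values for extreme clusters. `k = 0` returns exactly 1.

Significant clusters on one scaffold whose ordinal intervals overlap *or
touch* (adjacent ranks) are unioned transitively into *enriched regions*.
Region bp bounds run from the first member gene's start to the last member
gene's end; each region reports its distinct labelled genes and the minimum
member P-value. An optional `top_regions` keeps only the m regions with
smallest minimum P; by default all merged regions are reported, which is a
reproducible superset of any hand-highlighted selection. Region summaries
report total length, percent of summed scaffold length, and percent of the
genome's labelled genes inside regions, percentages rounded to one decimal.

The label is a parameter: `cazyme` scores clusters against the full CAZyme
census, `pcwde` against the plant-cell-wall-degrader subset; both runs are
meaningful and supported.

## Telomere scan

Telomeric repeats are short tandem motifs at chromosome termini; the
default unit is TTAGGGG. On the forward strand of a correctly oriented
scaffold the forward motif accumulates at the 3′ end and its reverse
complement (CCCCTAA) at the 5′ end. `scan_terminus` searches a terminal
window (default 500 bp) for the longest head-to-tail run of motif copies —
a naive quadratic scan, exact for these window sizes — and calls a hit at
`min_copies ≥ 3`. Matching is exact by default; a per-copy mismatch
allowance exists (default 0) but no variant model is assumed, and `N` bases
never match. Sequences shorter than the window are scanned whole rather
than rejected. A scaffold with hits at **both** termini is a putative
chromosome; scaffolds without sequence are classified unknown.

The window and copy thresholds are package defaults, chosen so that a
genuine terminal array (tens to hundreds of bp of tandem repeat) is always
caught while a single chance motif occurrence (expected ≈ `window/4^7` per
terminus for a 7-mer) never is. Three tandem copies by chance in a 500 bp
window is vanishingly rare (~1e−9 per terminus).

## Sub-telomeric classification

A region's distance to the nearest chromosome end is
`min(region.start, scaffold_length − region.end)` — measured from the
region *edge*, so any overlap with the terminal window counts ("within
200 kb" read inclusively). The cutoff defaults to 200,000 bp, inclusive.
Distances are measured from the scaffold end, not from the telomere array
itself; on assembled scaffolds with terminal arrays the two differ by at
most the array length. Regions on scaffolds not called putative chromosomes
are reported non-sub-telomeric with an explanatory note.

## Adjacency and paralogy

Adjacent enzyme genes are maximal runs of consecutive label-positive
ordinals (length ≥ 2), regardless of strand or intergenic distance — the
run definition is purely gene-order based, and a triplet is one run, not
two pairs.

To ask whether a run is explained by tandem duplication, each within-run
protein pair is globally aligned (Needleman–Wunsch; match +1, mismatch −1,
linear gap −2) and called paralogous at ≥ 30% identity (identical columns
over alignment length, gap columns included in the denominator) and ≥ 50%
coverage (columns where both sequences have residues, over the shorter
sequence length). The traceback tie-break is fixed — diagonal, then gap in
the second sequence, then gap in the first — so identity values are
deterministic. The thresholds are a conventional coarse homology heuristic
(the twilight zone for confident homology from identity alone starts near
30%); both are configurable, and a precomputed paralog-group table can
override alignment entirely. Affine gaps were deliberately not used: the
screen separates near-identical duplicates from unrelated proteins, a
regime where linear gaps are ample and the fully disclosed scoring is
easier to reproduce. Runs with missing protein sequences are left unknown
rather than silently negative.

## Annotation statistics

Gene length is the gene-feature span (UTRs included when annotated); the
average exonic length is reported alongside since published tables rarely
state which convention they use. Introns are the gaps between consecutive
exons of one mRNA; multi-isoform genes are represented by their longest
mRNA (by exonic length). The "genes ≥ 60 aa" count uses the representative
mRNA's summed exon length ≥ 3 × 60 bp as the coding-length proxy — the
pipeline consumes no CDS features. GC is counted over A/C/G/T only (N
excluded from the denominator). Averages are arithmetic means, reported
unrounded with rounded presentation values (lengths to integers,
introns-per-gene to 2 decimals).

## Comparative normalization

Cross-species category counts are displayed as percent of the per-category
(row) maximum — the largest count in each category becomes 100%, ties all
map to 100, all-zero rows stay 0. The operation is idempotent. Category
tabulation counts labelled genes and distinct CAZy families per category
and species; unknown category labels are bucketed as "other" with a
warning.

## Synthetic genomes

The simulator emits the statistical structure the analysis assumes, and
nothing more:

- Genes laid head-to-tail per scaffold with uniform lengths 500–3,000 bp
  and uniform intergenic gaps 100–2,000 bp — the scale of a compact fungal
  genome (mean gene ≈ 1.75 kb, ~1 gene per 2.8 kb).
- Background CAZyme labels by independent Bernoulli draws at rate
  371/10,013 ≈ 0.037 (the census density of a lignocellulolytic fungus);
  an exact-count mode places a fixed number of background labels without
  replacement when a test needs a deterministic census. A configurable
  fraction of labelled genes (default 114/371) is additionally marked
  PCWDE with a random category.
- Planted clusters put exactly the requested number of labels in a window,
  endpoints always labelled — ground truth for recovery tests.
- Telomere arrays are written verbatim over the terminal bases (reverse
  complement at 5′); scaffold backbone sequence is uniform random ACGT.
- Proteins are uniform random 20-letter sequences sized from exonic length;
  injected paralogs are per-residue mutated copies of their source protein
  (default rate 0.02, i.e. ~98% identity).
- Everything derives from one `numpy` generator seeded by the spec, so a
  spec is byte-reproducible; a truth JSON records every planted feature.

What the simulator does **not** emulate: codon structure, repeat content,
GC heterogeneity, assembly gaps, strand-correlated gene order, realistic
protein families. A green test on synthetic data therefore establishes the
*statistical and algorithmic* correctness of the pipeline (calibration of
the tail probability, recovery of planted structure, exactness of string
scans), not robustness to annotation noise in real genomes.

`permute_labels` is the matching null generator: it permutes label bundles
(flag + families + category travel together) uniformly across gene
positions, conserving counts — used to check that the hypergeometric tail
is calibrated against the permutation distribution it models.

## Numerical and degenerate-input choices

- Tail probabilities are clipped into (0, 1]; `k ≤ 0` short-circuits to 1.
- Significance and sub-telomeric cutoffs are inclusive (≤).
- Merge treats ordinal-adjacent clusters as touching (`next.first ≤
  prev.last + 1`).
- BED scores are `−10·log10(min P)` capped at 1000.
- Scaffolds with no genes contribute length but no clusters; scaffolds with
  < 2 labelled genes yield no candidates.
- The pipeline bundle is deterministic by construction: no timestamps in
  the log, sorted JSON keys, and the output directory is excluded from the
  echoed parameters so identical analyses in different directories compare
  byte-identical.

## Known limitations

- The cluster statistic ignores gene length and intergenic distance; a
  "cluster" of huge genes spans more bp than the same ordinal window of
  small genes.
- Overlapping candidate windows are counted separately before merging;
  both the candidate count and the merged-region count are reported since
  either may be the quantity of interest.
- The paralogy screen is a coarse identity filter, not a phylogenetic
  orthology analysis; it cannot distinguish ancient paralogy from
  convergent domain composition.
- Telomere detection assumes arrays lie within the terminal window of a
  correctly assembled scaffold; interstitial telomeric repeats are out of
  scope.
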