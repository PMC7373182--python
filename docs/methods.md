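# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Expression

Counts `k_ij` (gene i, sample j) are normalized by median-of-ratios size
factors: `s_j = median_i k_ij / g_i`, where `g_i` is the geometric mean of
gene i across samples and the median runs over genes with no zero count
(an even-length median is the mean of the two middle values). Size factors
are not rescaled afterwards; normalization divides each column by its
factor. Scaling one sample's column by `c` multiplies its factor by `c`
*relative to the others* — the per-gene geometric means absorb `c^(1/m)`
as a constant common to all factors, which leaves all between-sample
expression ratios unchanged.

Differential expression is a two-sided Welch (unequal-variance) t-test on
`x = log2(normalized + 1)`, chosen because group variances in small
clinical cohorts are rarely equal and the pseudocount handles zeros
deterministically. The fold change is `mean(x | case) − mean(x | control)`
in log2 units, with the alphabetically first condition label as control.
Benjamini–Hochberg adjustment runs across all tested genes, including
degenerate rows: all-zero genes get p = 1 and log2FC = 0; zero
within-group variance in both groups gives p = 1 for equal means and the
smallest positive float (with a `degenerate` flag) for unequal means,
avoiding 0/0.

The default filter keeps |log2FC| > 0.75, P < 0.05 and BH-adjusted
P < 0.45. The FDR cut-off is deliberately permissive: in small-cohort
candidate screening the P-value carries the primary stringency and an
aggressive FDR cut would underpower the downstream evidence integration.
All three thresholds are plain dataclass fields.

Null behaviour: Welch p-values on log-transformed negative-binomial counts
with 7 vs 7 samples are only asymptotically uniform; at 2000 genes a
Kolmogorov–Smirnov test against U(0,1) typically passes at p > 0.01 but
can be marginal for some random studies. This is inherent to running a
t-test on skewed count data and is one reason the thresholds are treated
as screening cut-offs, not error guarantees.

## Conservation

Ortholog candidates come from standard 12-column BLAST tabular input and
are kept when e-value < 0.01 (strict) and identity ≥ 80% (inclusive),
evaluated per HSP; the best hit per subject is retained (lowest e-value,
ties by bitscore then subject id). E-values are taken from BLAST, not
recomputed. The built-in local aligner (Smith–Waterman, affine gaps) uses
BLASTN-like defaults — match +2, mismatch −3, gap open −5, extend −2 —
with identity defined over alignment columns including gaps, matching the
filter's input semantics. Inputs are capped at 20 kb per sequence to bound
the O(nm) cost; beyond that, users should run BLAST itself. When an
effective search-space size is supplied, a Karlin–Altschul-style e-value
`E = K·mn·e^(−λS)` is attached with λ solved for the scoring scheme under
uniform base composition and K fixed at 0.1 — an order-of-magnitude aid,
not a replacement for BLAST statistics.

## Interaction scanning

An RNA–RNA duplex is modelled as an antiparallel local alignment: the
query is reversed so both molecules are processed 5′→3′, and aligned
columns are scored +5 for Watson–Crick pairs, +1 for G:U wobble, −3
otherwise, with affine gaps (first gapped position −9, each further −4).
Reported intervals are 0-based half-open in each molecule's native 5′→3′
coordinates. Suboptimal, non-overlapping hits are produced by masking the
optimal hit's target footprint and re-aligning, down to the reporting
threshold or a per-pair cap (10).

Each hit carries an additive energy: −3 kcal/mol per G:C, −2 per A:U, −1
per G:U, summed over paired columns. This has no stacking or loop terms,
so the −72 kcal/mol default threshold operates on this model's scale and
corresponds roughly to a ≥29-bp perfectly paired duplex; users wanting the
stringency of a nearest-neighbour model must recalibrate.

Long queries are tiled into 50-nt snippets with step 25 (50% overlap), so
any site up to 25 nt is always wholly inside some window; a step of 50
reproduces non-overlapping tiling. Trailing windows shorter than 20 nt are
replaced by a full-width window anchored at the sequence end, so coverage
is complete for any sequence at least 20 nt long, and the window at offset
0 is always kept. Snippet hits are back-mapped to full-sequence
coordinates; hits on the same target with overlapping query intervals are
merged (interval union, maximum score, most negative energy, maximum
paired count). Score and energy thresholds are applied per hit before
merging. mRNA scans apply both the score (≥160) and energy (≤−72)
thresholds; miRNA scans apply only the score threshold (≥120) and skip
snippeting since miRNAs are ≤30 nt. Note that under this matrix a perfect
22-nt miRNA duplex scores 110, so the 120 threshold effectively demands
≥24 paired positions — appropriate for near-full complementarity
screening, not seed-only sites.

External protein-interaction predictions are consumed as a table and
filtered at star rating ≥ 2.5 (inclusive) and discriminative power
strictly > 75%.

## Network and sponge logic

The knowledge network is an undirected `networkx` graph: nodes are typed
molecules (lncRNA, mRNA, miRNA, protein, TF) carrying DE status, log2FC
and annotation terms; edges carry evidence ({validated, predicted}) and
provenance sets, with parallel records collapsed by union. Undirected
edges reflect that source databases mix directed and undirected evidence;
regulation direction appears only in the report. Conflicting types for one
id are a hard error rather than a silent overwrite. GML export writes
primitive attributes (sets are semicolon-joined) and round-trips through
`read_gml` attribute-for-attribute.

Sponge inference is pure set algebra over gene symbols: `T` is the union
of validated targets of the predicted miRNAs, and the candidate classes
are `T∩D`, `T∩P` and `T∩D∩P`. No expression-direction (anti-correlation)
constraint is imposed, and identifiers are used as given — harmonization
across databases is the user's responsibility.

## Enrichment

For query size n from universe N, a term with K universe genes and k of
them in the query scores `p = P(X ≥ k)`, X hypergeometric — equivalent to
a one-sided Fisher test on the 2×2 table. The default universe is the set
of genes actually tested for expression, not the genome: genes that could
never have been called are not valid background. Terms with fewer than two
universe genes are skipped; query or term genes outside the universe are
dropped with warnings. BH adjustment runs across tested terms.

## Promoter analysis

The promoter is −2000..+500 bp around the TSS, strand-aware: plus-strand
genes use the genomic window `[tss−2000, tss+500)` directly; minus-strand
genes use `[tss−499, tss+2001)` reverse-complemented, so the output always
reads 5′→3′ relative to transcription and is exactly 2500 nt unless
truncated at a chromosome end (truncation is flagged). The gene-level TSS
is the 5′-most position on the gene's strand.

PWMs are count matrices converted to log-odds against a uniform background
(0.25 each, configurable) with pseudocount 0.01. Every window on both
strands (default) is scored and converted to a dissimilarity
`100·(S_max − S)/(S_max − S_min)`; hits at or below the maximum
dissimilarity are reported, with offsets as leftmost positions on the
forward promoter sequence. The formula is invariant to affine rescaling of
the log-odds, so matrices from different sources are comparable. At the 0%
default only windows attaining the matrix maximum are reported; columns
with tied maxima accept every tied base (degenerate consensus), which the
formula forces. N bases contribute the column minimum, so stringent scans
reject windows containing them. The final step joins promoter-binding TFs
with protein interaction partners; TFs present in both layers are the top
regulatory candidates.

## Synthetic data

The generator emulates a small two-group RNA-Seq study: negative-binomial
counts (variance `μ + φμ²`, gene-wise baseline means log-uniform on
20–2000, dispersion φ = 0.1) with 7 samples per group and 10% of genes
planted at |log2FC| = 2 — overdispersion comparable to a homogeneous human
cohort, and a design small enough that test power is a real constraint, as
in the clinical datasets this protocol targets. A random genome hosts
non-overlapping genes on both strands; the designated lncRNA carries a
50-nt complementary site for one mRNA (with ~10% of positions converted to
G:U wobble where chemistry allows, to exercise wobble scoring), full
complements of two 26-nt miRNAs (at most one wobble each, keeping the
planted score ≥126), a validated-target table in which those miRNAs target
the same mRNA, a forced up-regulation of that mRNA, and a 10-bp TF
consensus stamped into its promoter at a fixed offset. Every output is a
pure function of the seed.

What the fixtures do *not* emulate: read-level sequencing artifacts,
library-composition biases beyond size factors, correlated genes, isoform
structure (one transcript per gene), secondary-structure accessibility of
duplex sites, and real database identifier noise. Passing tests therefore
demonstrate that the machinery recovers the planted signal classes at the
documented margins — not that the thresholds are optimal for any real
tissue.

## Problem sizes and determinism

Default analyses run in seconds on one CPU: the simulated study uses 2000
genes, a 200-kb genome with ~25 genes, a 1200-nt lncRNA against 20
transcripts, and recovery statistics average 10–20 replicate simulations.
All randomness flows through `numpy.random.default_rng` seeded from a
single integer; pipeline runs are byte-deterministic for a fixed seed and
configuration (the manifest records version, seed and every threshold).
Candidate ranking breaks ties by FDR then lexicographic id, and every
table is written in a sorted, stable order.

## Known limitations

- The duplex energy model is additive per pair; its threshold is not
  comparable to nearest-neighbour free energies.
- The aligner reports one optimal alignment per iteration; co-optimal
  alignments are resolved deterministically by the alignment engine, not
  enumerated.
- Enrichment ignores the ontology graph (no true-path propagation).
- The miRNA score threshold excludes seed-only target sites by
  construction (see above).
- No identifier mapping: all inputs must share one gene-symbol namespace.
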