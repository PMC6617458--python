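# Methods

This note records the models and procedures implemented in `chitomics`,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Taxonomic classification

Reads are assumed merged and quality-filtered upstream; the pipeline
config carries the upstream merge settings (length window 100–500 bp,
minimum overlap 100 bp, quality threshold 30) as provenance only.

Each read is translated in six frames under the standard genetic code
(stops rendered `*`, codons containing `N` rendered `X`, trailing partial
codons dropped). Every 9-mer window made only of the 20 standard residues
is looked up in the peptide index; windows crossing a stop or a
non-standard residue (B, J, O, U, X, Z) yield nothing — non-standard
residues break windows rather than acting as wildcards, the simplest
defensible contract. I and L are treated as distinct residues; if the
reference database conflates them this is a divergence risk to be aware
of.

The index maps each 9-mer to a single taxid: the LCA of all reference
proteins containing it. Storing one LCA per k-mer (rather than the full
taxon list) is the Unipept-style memory contract and preserves the input
the consensus step needs. Building is associative LCA folding, so adding
reference proteins can only move a key's value rootward (a tested
invariant). k = 9 is the default and is configurable.

Per-read consensus: hits are pooled across the six frames (no per-frame
voting), root-level hits are discarded as uninformative, and the
aggregation descends from the root into any child whose subtree carries
at least a fraction *f* of the current node's hit weight (hits at a node
count toward its own subtree), stopping when no child qualifies. The
threshold default is *f* = 0.8; values ≤ 0.5 are rejected because two
children could qualify simultaneously, and *f* = 1.0 reduces exactly to
the LCA of the surviving hits (a tested equivalence). A small float
tolerance (1e-9 absolute on the weight comparison) keeps exact-boundary
cases such as 8 of 10 hits at *f* = 0.8 inclusive.

Genus tables count each assigned read at its genus ancestor; assignments
above genus are excluded from the table but retained in the per-sample
library size (total assigned reads), which is the normalization
denominator for relative abundances.

## Functional profiling

ORF extraction is a transparent stand-in for a gene caller: all maximal
stop-free translated stretches ≥ 30 aa across six frames. Real gene-caller
and profile-search outputs can be ingested directly through the
`domtblout` reader, which maps target → read id, query → family,
i-Evalue → e-value and the hmm from/to pair → model-coordinate span.

Match filtering keeps records with e-value ≤ 1e-10 and coverage ≥ 60%,
both inclusive. Coverage is measured on the profile model,
(to − from + 1) / model length — the standard convention for gene-targeted
profile databases; the denominator choice is configurable in spirit but
model coverage is the shipped behaviour. Counting deduplicates to one
count per (read, family): multiple domains of one read on one family
count once, while one read may count toward several families. Whether to
count reads or domains is not uniquely determined by common practice;
per-read counts were chosen as the more conservative option.

Genome equivalents follow the MicrobeCensus contract (GE = total bases /
AGS) with a transparent single-copy-marker rate estimator: a marker of
length L aa occupies 3L bp per genome, so AGS_j = 3·L·reads/hits_j per
marker, combined by geometric mean over markers with hits. This is not a
port of MicrobeCensus; callers may supply an externally estimated AGS
instead.

RPKG divides the deduplicated count by the model length in kilobases and
by the genome equivalents. Because reads are nucleotide, the default
converts the amino-acid model length by ×3/1000; an `aa` length unit is
available as a switch since the convention is not universal. RPKG is
invariant under uniform depth scaling (counts and GE scale together) — an
exact algebraic identity, tested to 1e-12.

Registry model lengths (e.g. GH19 = 215 aa, narG = 1250 aa) are artifact
defaults: profile databases publish per-model lengths and users should
load their own registry YAML for real data. The genes hao, nor, nasA and
nir are deliberately absent — no public profile models back them.

## Count statistics

*Abundance filter.* A feature is kept if its CPM (count/library size
× 1e6) is ≥ 4 in ≥ 4 samples, both thresholds inclusive; 4 samples
matches the replicate number of the design.

*TMM.* The reference sample is the one whose 75th-percentile count
proportion is closest to the sample mean. Per sample, features zero in
either member of the pair are excluded; M-values are doubly trimmed (30%
on M, 5% on A) by rank, averaged with inverse-asymptotic-variance
weights, and factors are rescaled to geometric mean 1. Pairs with
identical composition short-circuit to a factor of exactly 1.

*qCML dispersion.* Counts are quantile-adjusted to the geometric-mean
library size by exact mid-p quantile matching under the current NB (or
Poisson at φ = 0) model — with equal library sizes the adjustment is the
identity, a tested property. Where the discrete CDF saturates at 1.0 in
floating point the map falls back to mean-ratio scaling. The common φ
maximizes the conditional log-likelihood given group sums, summed over
features and groups with ≥ 2 replicates, via a 31-point log-spaced grid
on [1e-6, 10] plus bounded refinement between the bracketing grid points;
adjustment and estimation are iterated once (starting from φ = 0).
Tagwise values maximize the per-feature likelihood plus `prior_df`
(default 10) times the mean per-feature likelihood, shrinking noisy
features toward the common value.

*NB exact test.* Conditional on the total of the two (quantile-adjusted,
rounded) group sums, the two-sided p-value is the total probability of
all splits no more likely than the observed one under the NB convolution
(group sum of n replicates ~ NB with size n/φ). Probabilities are
compared in log space with a 1e-8 relative tolerance so exactly
symmetric splits tie correctly; a perfectly balanced split yields p = 1.
The implementation enumerates all splits directly (vectorized), so it
*is* the enumeration — the test-suite oracle recomputes it independently
through linear-domain pmf sums. Log2 fold changes use normalized group
means with a 0.125 pseudo-count, second group level versus first (levels
taken in order of first appearance, so `PS` then `Chitin` in the default
design).

*Quasi-Poisson GLM.* Gene-family counts are modeled on the raw count
scale with a log link, intercept + treatment, and a per-sample
log-exposure offset (log GE; the per-family model-length term is constant
across samples and cancels in the treatment contrast) — equivalent in
expectation to modeling RPKG but statistically better behaved than
fitting transformed values. IRLS runs at most 50 iterations to 1e-10;
non-convergence is flagged and reported as a NaN p-value. The dispersion
is Pearson X²/(n − 2) and the treatment coefficient is tested two-sided
against t with n − 2 df. All-zero features are reported as uninformative
(p = 1).

*BH.* Standard step-up, returned in input order, applied separately
within each analysis family (genus table; gene tables), mirroring
per-table testing.

*Distances and PERMANOVA.* Bray–Curtis on relative abundances (columns
scaled to sum 1). The pseudo-F uses squared distances:
SS_total = Σ_{i<j} d²/n, SS_within summed per group, F =
(SS_between/(g−1))/(SS_within/(n−g)). When the number of distinct
relabelings (the multinomial coefficient) is ≤ 10,000 all are enumerated
and p is the exact fraction with F ≥ F_obs (for 4 + 4 this is 70
relabelings, so the minimal p is 2/70 = 1/35 because each labeling and
its swap give the same F); otherwise labels are shuffled with a seeded
generator and p = (count + 1)/(n_perm + 1). F comparisons use a 1e-12
tolerance to count exact ties; perfectly separated groups give F = ∞
and still compare correctly. The distance metric is a package choice
(Bray–Curtis is the common default for this workflow); the functions
accept any distance matrix.

*Dispersion homogeneity.* Principal-coordinate embedding of the distance
matrix (Gower-centered, negative eigenvalues truncated at 0), per-sample
distance to the own-group centroid, and a permutation F-test on those
distances. When all distances are equal the F is defined as 0 (no
dispersion signal) and p = 1.

## Synthetic data

The generator emulates the study design the statistics assume: two
treatments × 4 replicates, 10 genera, 10,000 reads × 200 nt per sample,
error-free by default, genus fold changes applied to the Chitin group
and renormalized, Dirichlet replicate noise with concentration 200
(giving a replicate CV of roughly 0.3–0.5 at percent-level abundances,
the scale of reported genus standard errors), and gene-family count
shifts of a few fold. The default spike magnitudes (3.4×, 7.6×, 0.4×)
mirror reported genus shifts under chitin amendment; the spiked genera
sit at 2–3% base abundance, within the abundance range of the genera
those magnitudes come from. Base abundances are a fixed decreasing
simplex (0.30 … 0.02).

Deliberate idealizations, and what they mean for the tests:

- **Disjoint proteomes.** Genera share no 9-mer (rejection-resampled), so
  every error-free read classifies to the truth exactly. Recovery tests
  therefore validate the *machinery* (translation, indexing, consensus,
  roll-up), not classification accuracy on real, overlapping reference
  databases, where assigned fractions are far lower and consensus
  assignments sit higher in the tree. The optional overlap mode shares
  proteins between two species per genus to exercise sub-unanimous
  consensus.
- **Tiny genomes** (~16 kb: the CDS plus 2% neutral spacer) keep marker
  hit counts high, so AGS recovery within 10% reflects estimator
  correctness, not the sampling noise floor of real 2–8 Mb genomes at
  modest depth.
- **No indels, chimeras or quality decay**; substitution errors only,
  constant quality scores.
- Profile matches are drawn at configured pass/fail rates around the
  filter thresholds rather than from sequence similarity; the
  "filter recovers truth exactly" test validates bookkeeping, not
  homology search.

Statistical power and type-I studies iterate on count-level
Dirichlet-multinomial simulation (`simulate_genus_count_table`). On the
disjoint-proteome reference, classification reproduces true genus counts
exactly (verified end-to-end separately), so the count-level shortcut is
lossless while letting 20-seed studies run in seconds.

Everything is deterministic given the seed: same seed, byte-identical
corpus.

## Problem sizes used in the validation suite

The shipped validation classifies one full default corpus (80,000
reads), runs 20 count-level studies for power/false-positive rates,
1,000-feature null simulations for each test's type-I error, and exact
enumeration checks for all group totals ≤ 30 — sizes chosen so the whole
suite completes in well under a minute per component on one CPU while
leaving the binomial/enumeration bounds tight enough to be meaningful.

## Known limitations

- The consensus descent rule is this package's concrete, documented
  choice; metagenome pipelines differ in their filtering of
  low-frequency k-mer hits, and no additional frequency filter is
  applied beyond root-hit discard.
- qCML here implements the named method with exact-quantile adjustment
  and a grid+refinement optimizer; a different implementation's tagwise
  shrinkage weighting will differ in detail.
- The quasi-Poisson t-reference with n − 2 df is approximate at n = 8;
  the null simulations show rejection rates of ~0.04–0.05 at nominal
  0.05.
- PERMANOVA exhaustive mode enumerates label multiset permutations; for
  designs beyond ~10,000 relabelings it falls back to sampling, where p
  has resolution 1/(n_perm + 1).
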