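# Methods

This note documents the models implemented in `tdnakit`, the parameter
choices that matter, the synthetic-data generator's scope, and the numerical
conventions and limitations a user should know before trusting a result.

## Locus model and coordinate conventions

A tDNA locus is (scaffold, start, end, strand, isoacceptor type, pseudogene
flag), with 0-based half-open coordinates and start < end regardless of
strand.  All readers convert at the boundary: tRNAscan-SE tabular records
are 1-based inclusive and encode the minus strand as begin > end (normalised
by swapping); GFF3 is 1-based inclusive; BED6 is already half-open.  The
half-open convention makes the consecutive-locus gap the plain difference
δᵢ = aᵢ₊₁ − bᵢ, with δ = 0 meaning directly abutting and δ < 0 an overlap.
Locus length outside 50–600 nt triggers a warning, not an error (tRNA genes
with long introns and fragmented pseudogenes both occur).  Isoacceptor
homogeneity is always at the amino-acid level, never the anticodon; SeC,
Sup and Undet act as three extra types.  Pseudogene status is taken solely
from the detector's annotation — no re-scoring is attempted.

Overlapping or duplicate loci are retained unmerged.  There is no
principled merge rule for near-identical detector calls, and a negative gap
satisfies any positive cutoff, so overlapping loci always co-cluster; this
choice is recorded here because it can inflate pair counts on assemblies
with redundant contigs.

## Cluster calculus

A cluster is a maximal run of consecutive loci on one scaffold with every
internal gap strictly below the cutoff (default 1000 nt); the boundary case
matters and is pinned by tests (999 clusters, 1000 does not).  Runs of one
locus are isolated; the *fraction clustered* of a genome is (loci in
clusters of size ≥ 2) / (all loci).  Consecutive pairs within clusters are
classified by homogeneity, by orientation — equal strands parallel; the
anti-parallel classes are keyed by their strand signs (+,−) and (−,+), with
the conventional "head-to-head"/"tail-to-tail" labels attached only for
reporting, because arrow glyphs are used inconsistently in the literature —
and by pseudogene involvement (gene–gene, gene–pseudo, pseudo–pseudo).  In
the co-occurrence matrix the mixed gene–pseudo pairs are counted in the
pseudogene-involved stratum, and relative abundances are normalised by the
genome's total pair count; both are conventions, flagged in report
metadata.

## Randomization null

The null hypothesis is uniform, independent placement: the locus collection
is removed and re-inserted, each locus keeping its length, type, flags and
strand.  A scaffold is chosen with probability proportional to the number
of admissible start positions (L − ℓ + 1) for the locus's length ℓ, the
start uniform on that range, and any placement with two overlapping
relocated loci is rejected wholesale and redrawn.  At realistic tDNA
densities the acceptance rate is ≈ 1; the sampler refuses pathological
densities after 10⁴ attempts rather than silently biasing the null.
Relocation is genome-wide, not per-chromosome, and strand is preserved —
neither matters for a strand-blind distance statistic, but both are stated
choices.

Two statistics are supported: the number of clustered loci and the number
of consecutive clustered pairs (the default, since the pair count is the
quantity with a clean analytic sparse-regime approximation).  The empirical
enrichment p-value is p = #{y⁽ⁱ⁾ ≥ x}/N, with a (+1)/(N+1) pseudocount
variant available but off by default so that p = 0 and p = 1 are attainable
at finite N.  Replicates run from N_min = 50 up to N_max = 1000, stopping
early once the running p-value reaches 0.2 — large p-values need no
resolution.

Because the pair count is a small integer, the counting p-value is discrete
and conservative under the null (stochastically larger than uniform).
Calibration studies therefore use the randomized p-value
p\* = (#{y > x} + U·(1 + #{y = x}))/(N + 1), U ~ Uniform(0,1), which is
exactly Uniform(0,1) for any discrete statistic when observation and
replicates share a distribution.  The test suite KS-tests p\* and checks
the plain p for validity (P(p ≤ α) ≤ α); the same distinction applies to
Fisher's exact test below, whose p-values on discrete 2×2 tables are
likewise conservative, so its null-simulation test asserts validity, not
uniformity.

The analytic oracle: for n point loci uniform on length L, each of the
n − 1 consecutive spacings falls below d with probability
≈ 1 − (1 − d/L)ⁿ⁻¹, giving an expected pair count of
(n − 1)(1 − (1 − d/L)ⁿ⁻¹).  (The exact order-statistics exponent is n; the
difference is < 0.1% in the regimes tested.)  Monte-Carlo runs of the
sampler agree with this within 5% at n = 200, L = 10⁷, d = 1000.

## Fisher homogeneity test

Whether pseudogene filtering changes the homogeneous/heterogeneous pair
proportion is tested with Fisher's exact test on the 2×2 table
{homogeneous, heterogeneous} × {all tDNAs, intact genes only}, two-sided
via `scipy.stats.fisher_exact`; a zero margin is reported as p = 1 with a
degenerate flag.  The suite verifies exact agreement with the direct
hypergeometric summation on every table with margins ≤ 20.

## Scaling fits

Counts versus genome size are fitted by OLS of log₁₀(count) on
log₁₀(size), separately for intact genes, pseudogenes and all tDNAs;
zero-count genomes are dropped pairwise (logged), and fewer than three
usable genomes is an error.  The reported slope standard error is the
classical OLS one, matching how ±-uncertainties on such exponents are
conventionally quoted; Spearman's ρ on raw counts is reported alongside the
log-log Pearson r because published correlation summaries rarely name the
estimator.  Parameter-recovery simulations plant exponents
{0.658, 0.930, 1.615} with lognormal noise; note that the ±2·stderr rule
under a correctly specified model with 30 genomes covers the truth with
probability P(|t₂₈| ≤ 2) ≈ 0.945, not 0.95 — a coverage statement at
exactly 95% needs the t critical value 2.048.

## Synteny

Flank contexts are the ≤ k (default 5) nearest protein-coding genes per
side, on the same scaffold and by default the same strand as the tDNA.
Upstream/downstream are defined in the tDNA's reading direction (for a
minus-strand locus the genomic right side is upstream); a `genomic`
orientation switch is provided since either frame is defensible.  Five
genes per side is a pragmatic trade-off: enough local signal to survive
incomplete annotations, small enough not to span unrelated regions.

Single-sided linkage needs one ortholog pair anywhere between the two
contexts; two-sided linkage needs one within the upstream lists of both
loci and one within the downstream lists, each side evaluated in its own
species' frame, which places both tDNAs between matched genes.  Two-sided
implies single-sided by construction, and the suite asserts it.  The window
mode (for genomes where flank annotation order is unreliable) calls a locus
pair syntenic when ≥ 2 *distinct* ortholog pairs fall within ±40 kb of
both loci; distinctness is the size of a maximum bipartite matching, so a
single promiscuous gene family cannot reach the threshold alone.  tDNA
identity (type/anticodon) is deliberately ignored throughout — the question
is whether *a* tDNA is retained at the position.

A locus of species A counts as conserved in B if at least one B locus is
linked to it (partners recorded, counted once), so the (A, B) cell's
denominator is A's locus count regardless of B and the matrix need not be
symmetric.  Fractions are reported at two decimals in tabular output;
internal values are exact.  Conservation versus evolutionary distance is a
plain OLS on the per-ordered-pair fractions, with optional averaging of the
two directions of each species pair and an exclusion list for species whose
locus counts distort the comparison.

## Synthetic-data generator

The generator produces the arrangement features the statistics consume, and
nothing else — no nucleotide sequence, no codon usage, no repeat content.

*Genomes*: cluster sizes are 1 + Geometric(p) (support ≥ 2, default
p = 0.45), matching the rapid, approximately exponential decay of observed
cluster-size histograms; heavier tails can be emulated by lowering p.  The
requested clustered fraction (default 0.4, in the range spanned by real
genomes) is hit exactly by trimming the last cluster.  Within-cluster gaps
are uniform on [0, cutoff); between-entity gaps are cutoff plus a
multinomial share of the scaffold's slack, so the planted partition is
*exactly* what the detector must report — recovery tests are equality
tests, not statistical ones.  Isoacceptor frequencies default to uniform
over the 20 amino acids with rare (0.02 weight) SeC/Sup; pseudogene status
is i.i.d. Bernoulli (default 0.1); strands are i.i.d. with P(+) = 0.5.
Real genomes violate most of these independence assumptions (tandem
duplications correlate type and strand), so passing tests certify the
*measurement* machinery, not any biological claim.

*Species pairs*: species A places each tDNA between `flank_genes` genes per
side; species B keeps each neighbourhood's genes (orthologous with
probability `ortholog_retention`) and keeps the tDNA with probability
`retention`, relocating the rest into fresh neighbourhoods of
non-orthologous genes.  Planted retention is thus recoverable exactly by
two-sided linkage on the defaults; `extra_ortholog_noise` adds spurious
many-to-many relations to probe false-positive behaviour.  Neighbourhoods
are spaced 100 kb apart so ±40 kb windows never bleed into each other.

*Scaling cohorts*: genome sizes log-uniform on [10⁷, 10¹⁰]; counts
C·sizeᵅ with lognormal noise of 0.2 dex, roughly the scatter real
count–size relations show.  Counts are left unrounded so the planted
exponent is the exact truth of the regression model.

## Problem sizes in the test suite

The default suite uses genomes of 40–300 loci, 100 random instances (n ≤
500) for the brute-force cluster oracle, 500 meta-replicates × 200
replicates (10⁶-nt genome, 50 loci) for null calibration, 10⁴ replicates
for the Monte-Carlo/analytic comparison, 500 cohorts × 30 genomes for
exponent recovery, 400-locus species pairs for retention recovery, and
every 2×2 table with margins ≤ 20 for the Fisher cross-check.  The
whole suite runs in well under five minutes on one core.

## Known limitations

* No intron handling: a tRNA gene with a long intron is one interval.
* No organellar support; every input sequence is treated independently,
  including unplaced/random assembly fragments.
* The null model is uniform — no GC-, chromatin- or replication-timing
  matching; observed enrichment over this null does not identify the
  mechanism.
* Single-sided linkage saturates on large gene families (many-to-many
  orthology); results should lean on the two-sided or window modes.
* Conservation fractions are upper bounds on true syntenic retention:
  linkage does not verify that the *same* tDNA survived, only that some
  tDNA occupies the region.
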