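# Methods

`tepra` analyses the evolution of enhancer activity within a transposable-
element (TE) subfamily assayed by a massively parallel reporter assay
(MPRA). This note describes the models and procedures each stage
implements, the assumptions behind them, the synthetic study the package
ships for testing, and the known limitations of both.

## Coordinate and data conventions

All coordinates are 0-based half-open; BED output follows the same
convention; 1-based positions appear only in human-readable summaries.
Sequences are over `{A,C,G,T,N}`; `N` is excluded from identity fractions,
ti/tv counting, and motif windows. The backbone data structure is the
*reference alignment matrix*: every subfamily copy is globally aligned
pairwise to one reference copy (a consensus or reconstructed ancestor) and
the alignments are combined column-wise on the reference coordinates.
Insertions relative to the reference are dropped from the matrix (they are
retained by the window-extraction routine used for library design), and
columns in which fewer than 20% of copies have a base are masked out of all
downstream scans.

## Pairwise alignment

Global alignment uses the Gotoh affine-gap algorithm with default scores
match +1, mismatch −1, gap open −2, gap extend −0.5 (a gap of length L
costs open + (L−1)·extend). The defaults are conventional; nothing
downstream is sensitive to moderate changes, and they are configurable.
Traceback ties are broken deterministically — diagonal over gap-in-query
over gap-in-ref — so reruns are byte-identical. The implementation is
verified against exhaustive enumeration of all alignment paths for short
sequences.

## Motif model and scanning

Position weight matrices carry probabilities with a 1e-3 pseudocount
(renormalized) before log2 odds against a background (uniform 0.25 by
default). Scanning reports every window, on both strands by default, whose
score reaches the threshold derived from a p-value: the exact distribution
of the window score under the background is computed by dynamic programming
on an integer score grid (10⁻⁴ bits per unit), and the threshold is the
smallest score whose upper tail probability is ≤ p (default p = 1e-4, the
common scanner default). Window scores are evaluated on the same integer
grid, so thresholding is exactly consistent with the distribution. A
consequence worth knowing: for width-k motifs with 0.25^k > p no window can
pass — short motifs need a looser p.

The bundled JUN-like and DBP-like matrices are synthetic stand-ins built
from the canonical consensus 11-mers (AP-1 TGAnTCA core; DBP D-box
TTATGTAA), with per-position confidence 0.92–0.95 in the core and 0.65 at
the flanks. Real matrices in MEME minimal format can be supplied instead
and flow through every stage unchanged.

## MPRA enrichment scoring

Barcode counts are summed per element; elements with fewer than five total
counts in the DNA pool or in any RNA replicate are dropped. Counts are
converted to counts-per-million over retained elements, expression is RNA
CPM / DNA CPM per replicate, normalized to the arithmetic mean expression
of the basal promoter-only construct pooled over replicates, and the
enrichment score is the log2 of normalized expression. The per-element
score is the mean of per-replicate log2 scores (mean-of-logs; the replicate
reduction is a package choice made for symmetry and robustness to a single
outlying replicate). "Active" means score strictly greater than a named
threshold — 1.0 by default (more than twofold over basal), with a relaxed
0.5 labelling supported for low-activity contexts. Whether the ≥5-count
filter applies to barcode-level or element-level sums is ambiguous in
common usage; element-level sums are used here. Motif-mutagenesis effects
are score differences (mutant − native), i.e. log2 expression ratios;
groups are summarized by the fold change 2^(mean effect) and compared with
two-tailed Mann–Whitney U tests.

## Position-wise association (TE-WAS)

The aligned copies of a subfamily are treated like a GWAS cohort. At every
retained, polymorphic reference column the tested allele is the most common
A/C/G/T (ties broken alphabetically and flagged); copies carrying it are
"carriers", copies carrying another base are "non-carriers", and gaps/N are
missing. A two-sided Fisher's exact test on the carrier × active 2×2 gives
the position's p-value; positions with p < 5×10⁻⁵ are significant. Fisher's
exact test is used in place of a 1-df allelic chi-square — both are
two-sided tests of the same table, and the exact test is preferable at
subfamily sample sizes; this substitution is recorded in output metadata.
The implementation computes the hypergeometric summation directly, which
lets label-permutation calibration amortize the per-column work across
hundreds of permutations.

Motif-level follow-up sums the per-position information content
(2 + Σ p log2 p, uniform background) of significant positions inside each
motif placement and compares it with a null of 1000 uniform redraws of the
significant-position set from the tested positions, via a one-sided
one-sample t-test (null sample vs the observed value); motifs need p < 0.05
and at least 2 significant positions inside the span (the in-motif count
threshold is configurable; 2 is the package default). A complementary
presence test runs per-motif Fisher tests of motif hits in active vs
inactive elements with Bonferroni correction.

**Limitation — phylogenetic confounding.** Copies of a TE subfamily are
related by a tree. A motif loss on a deep branch is perfectly correlated
with every other substitution fixed on that branch, so position-level
association cannot distinguish causal from hitchhiking positions within a
single clade; causal positions only separate when losses recur
independently across the tree. The power tests therefore use a
shallow-structure synthetic subfamily (most divergence on terminal
branches); on deep-clade histories the scan's top hits can be hitchhikers,
which is a property of the method, not of the implementation.

## Tiled-MPRA deconvolution

Each tiled element is divided into s-bp steps (s = tile step, 10 by
default; tiles are 160 bp, final tile right-anchored). A tile's score is
modelled as the average of the latent step activities it covers plus unit
observation noise; with a Gaussian prior of variance 1/λ on step
activities, the MAP estimate is the ridge solution
x = (WᵀW + λI)⁻¹WᵀM, with W the tile-over-step averaging matrix. Two
penalties (λ = 1 and 50) are inferred and combined by unweighted mean (the
published tool's combine step is not specified precisely; the unweighted
mean is this package's definition). Combined step values are normalized by
subtracting the mean inferred value of shuffled basal elements (scores are
log-scale, so subtraction keeps basal at zero), then linearly interpolated
from step centers (j·s + s/2) to nucleotides with constant extrapolation
past the terminal centers. Element activity is the sum of nucleotide
values; peaks are maximal runs of positions more than 3 basal standard
deviations above the basal mean, with the SD computed over basal step
values. Note that with the averaging W all singular values are below 1, so
λ = 1 already shrinks the fit substantially — step estimates are
conservative and the two-λ average is smoother than the underlying
profile; the closed-form behaviours (single-tile value, one-step-per-tile
reduction M/(1+λ), shrinkage to zero) are exact.

## Conservation and neutral motif retention

Sliding 10-bp windows (step 1) on the consensus are scored per element as
the fraction of compared positions matching the consensus; an element is
dropped from a window when five or more of its positions there are gaps or
degenerate. Each window's element values are compared against the pooled
values of all windows with a one-sided (greater) Welch t-test, Bonferroni-
corrected over windows at 0.05. Zero-variance windows report p = 1 rather
than NaN. Windows conserved in every species are intersected, merged into
runs, and scanned for motifs fully inside.

The neutral motif-retention model asks: starting from an ancestral k-mer,
what is the probability that after substitution the site still matches the
motif? Per-site single-step probabilities come from the observed rates:
stay = 1 − s_ti − s_tv, transition = s_ti, each specific transversion =
s_tv/2, with s_ti and s_tv estimated by pooled counting of element-vs-
reference differences per species. The exact expectation sums, over every
k-mer that passes the scanner threshold (either strand), the product of
per-site probabilities of reaching it from the ancestral k-mer — computed
by enumerating all 4^k k-mers with vectorized accumulation (k = 11 is ~4M
k-mers, well within memory). Monte-Carlo simulation mutates each element's
motif region under the same model and records the fraction retaining the
motif; 1000 simulations by default. Observed retention is the fraction of
elements whose projected bases at the motif span still hit the motif,
excluding elements with gaps or degenerate bases in the span. Observed and
expected are compared with a two-sided one-sample proportion z-test.

Assumptions and their consequences: sites evolve independently with a
single substitution step (no rate heterogeneity, no explicit multiple-hit
correction). Because the rates are estimated from *net* differences,
recurrent and back mutations make the single-step expectation an
*overestimate* of true neutral retention; and because subfamily copies
share deep branches, the observed fraction has a much larger effective
variance than the binomial n suggests. On the package's own neutral
synthetic data the observed retention can therefore sit visibly below the
exact expectation without any selection. Both effects push in the
conservative direction for the biological question (they make *excess*
observed conservation harder, not easier, to obtain), but they should be
kept in mind when reading the proportion-test p-values.

## Annotation overlap

Annotation intervals are merged (bookended intervals coalesce) before use.
An element overlaps an annotation when at least 50% of its length is
covered. Subfamily-level enrichment builds a 2×2 in the style of interval-
level Fisher tools: elements overlapping / not overlapping, annotation
intervals not hit by any element, and a fourth cell estimating the
remaining annotation-sized slots in the genome (genome size / mean merged
interval length minus the other three cells); the construction is recorded
in output metadata since tool implementations vary. Strand is ignored;
elements on chromosomes absent from the annotation count as
non-overlapping. Motif association uses per-motif Fisher tests of presence
vs overlap with Bonferroni correction.

## The synthetic study

The generator emulates the two-phase history of an LTR subfamily. A random
360-bp root carries planted motif consensus k-mers (JUN-like at position
30 with effect +0.75 log2, DBP-like at position 70 with effect +1.20 log2
— effect sizes on the scale of the mutagenesis fold changes reported for
this class of experiment). The *transposition phase* is a Yule birth tree
grown to 28 leaves, each branch applying per-site substitutions
(s_ti = 0.02, s_tv = 0.01) and indels (rate 5×10⁻⁴ per site, geometric
lengths capped at 9). Each leaf — an "ortholog ancestor" — then enters the
*speciation phase*, evolving independently into seven primate-like species
with branch lengths 0.010 (human) to 0.040 (marmoset) substitutions/site
split 2:1 transitions:transversions. This yields 196 present-day elements
(~200) with root-to-tip divergence in the 7–25% range and an overall
subfamily divergence comparable to an old LTR subfamily.

Element activity is baseline 0.3 plus the sum of planted effects for
motifs actually present (presence is decided by the scanner, so
evolutionary losses and chance gains both count) plus Gaussian noise
(SD 0.25 log2). The library contains the motif-focused window ([0,160) on
the root, elements with <70 or >160 bp excluded), 160/10 tiles of ancestral
nodes, loss/gain mutagenesis fragments using the fixed replacement strings,
30 shuffled-root tiled negative controls (uniform shuffles; dinucleotide
composition is not preserved), and a basal construct. Every fragment gets
10 barcodes (basal 300). DNA counts are negative binomial (mean 100,
dispersion 0.1); RNA counts per replicate are negative binomial with mean
= realized DNA count × 2^activity, three replicates.

What the generator does *not* emulate: cell-type-specific trans
environments, chromatin or epigenetic silencing, sequence-composition-
dependent mutation (e.g. CpG hypermutability), selection, or realistic
indel hotspots. Passing the recovery tests therefore demonstrates that the
pipeline's inference machinery is correct under its stated noise model —
not that the biological conclusions would survive real-data confounders
such as batch effects or mapping artefacts.

## Numerical choices and problem sizes

Ridge systems are solved densely (step counts are tens). Fisher p-values
carry the customary (1+1e-7) relative tolerance when summing tables as
extreme as observed. The exact PWM score distribution uses a 10⁻⁴-bit
grid. The test suite runs the full synthetic study at its default size
(196 present-day elements); permutation calibration uses 500 label
permutations, association power uses 20 independent studies, window-test
specificity uses 100 seeds at 25 elements × 120 bp, and Monte-Carlo/exact
agreement uses 1000 simulations per configuration — sizes chosen so each
check has resolving power well beyond its tolerance while the whole suite
stays comfortably interactive.
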