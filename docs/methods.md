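# Methods

## Coordinate model

All interval arithmetic is 0-based, half-open (BED convention). Readers for
1-based fully-closed files convert at the boundary (`one_based=True`), so a
single convention holds internally. Cluster sets are merged on
construction: overlapping *and book-ended* intervals collapse, because a
cluster is a maximal run of enrichment and adjacency of two called
intervals is a tiling-resolution artifact. Strand is ignored everywhere;
the overlap score is a strand-agnostic footprint quantity. Validators
reject — never clamp — intervals outside chromosome bounds, naming the
chromosome, coordinates and (in file readers) the line.

## Co-localization score and its nulls

The score between cluster sets A and B is |A ∩ B| in bp, computed per
chromosome by a two-pointer sweep over the sorted disjoint interval arrays
and checked in the test suite against per-base boolean bitmaps.

**Randomization null.** Each iteration re-places one set (by default the
first argument; `b` or `both` by flag): per chromosome, the same number of
intervals with the same multiset of lengths, each start drawn uniformly
from its valid range, the joint draw rejection-sampled (default 1000
retries) until placements are pairwise disjoint. We additionally require a
≥ 1 bp gap: book-ended placements would merge on construction and silently
change the interval count, breaking the length-multiset invariant that
rejection sampling is meant to preserve. The loss of uniformity from
excluding exact adjacency is one configuration in ~L per interval pair and
is negligible at genomic scales. For sets too dense to place disjointly an
`allow_overlap` mode keeps collisions and merges them before scoring (total
bases may then shrink; the mode is surfaced, not silent). Randomization
preserves chromosome assignment: chromosome-specific base composition and
feature density make cross-chromosome shuffles a different (and stronger)
null than the score warrants.

**Empirical p.** The add-one estimator (1 + #{null ≥ obs}) / (n + 1),
standard permutation-test practice; p is never 0 and its floor is
1/(n_iterations + 1). Ties count in the tail, making the test valid
(conservative) under discreteness.

**Fisher's exact test.** The 2×2 table allocates every base of the genome:
a = |A∩B|, b = |A|−a, c = |B|−a, d = G−a−b−c. The one-tailed (enrichment)
p is the hypergeometric upper tail P(X ≥ a), computed with
`scipy.stats.hypergeom.sf` and verified against full enumeration of all
same-margin tables on small genomes. Treating autocorrelated bases as
exchangeable units makes this p anti-conservative — often astronomically
small on megabase genomes — so reports always pair it with the empirical p,
which is the recommended headline number. When the tail underflows double
precision the value is clamped to the smallest positive float rather than
reporting an impossible 0.

## Enrichment and co-occupancy

Fold increase is computed on bases (observed overlap with the feature-class
footprint over expected), matching the overlap score's own currency; a
feature-count reading of "enrichment" is available implicitly through the
bound-feature machinery. Two expectation modes are labeled explicitly:
`analytic` (|A|·|F|/G, the independence expectation) and `montecarlo` (mean
of the randomization null, which also yields an empirical p). On sparse
sets the two agree within ~10% at 1000 iterations (tested); on constrained,
dense sets the Monte-Carlo mean is the more honest reference.

A feature is *bound* at ≥ `min_overlap_bp` (default 1 bp) of overlap — the
weakest defensible criterion, deliberately a surfaced parameter since no
community standard exists for calling a discrete element "occupied" by a
cluster. Feature bodies are used as annotated; an optional `flank_bp`
extension (default 0) widens them symmetrically. Co-occupancy tabulates the
exact protein combination per feature; counts sum to the feature total and
percentages to 100 (raw reals — any rounding or truncation is display
policy, not computation).

## EM joint-molecule classification

The classifier codifies, as ordered deterministic rules, the geometric
criteria used when calling replication intermediates by eye on EM
micrographs (it consumes measured branch lengths, not images). One knob,
`rel_tol` (default 5%), defines when two lengths are "equal":

1. no junction, two branches → linear (excluded from JM tallies);
2. one three-branch junction → fork;
3. two junctions: four-branch → dHJ, three-branch → bubble (junction
   geometry only — no length criterion exists for dHJs);
4. one four-way junction with an equal branch pair (sister daughter arms)
   whose complementary shortest branch (the regressed arm) is no longer
   than the daughters → reversed fork;
5. else, if some pairing of the four branches into two opposite pairs
   gives equal sums — two through-going filaments of the same size
   crossing at the junction → hemicatenane;
6. else unclassified.

Rules use only length ratios, so classification is invariant to branch
order, uniform rescaling, and the nm→bp calibration (500 bp per 180 nm by
default). Rule 4 precedes rule 5 by construction: a perfectly symmetric
four-way junction is called a reversed fork, the more specific geometry.
The 5% default and the rule order are the genuinely open design choices
here; both are parameters or documented behavior, not baked-in constants.
Frequency tables report per-genotype percentages over the classifiable
(non-linear) molecule count.

## ChIP-qPCR

percent input = 100 · 2^((Ct_input − log2(input_dilution)) − Ct_IP). The
dilution correction is applied inside the formula and the dilution is a
required input column — it differs between protocols and cannot be
recovered from Ct values. Group comparisons default to the pooled-variance
Student's unpaired two-tailed t-test (Welch by flag); SEM = sd/√n with
n ≥ 2 enforced. No multiple-testing correction is applied; loci are
reported individually.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses assume at
budding-yeast scale: a 16-chromosome, 12,071,326 bp genome (the reference
chromosome lengths), 71 TERs of 4–6 kb, one 110–130 bp centromere per
chromosome, 275 tRNA genes of 70–100 bp, all placed without overlap; and
cluster sets with log-normal lengths (median 1 kb, log-sd 0.5 — a standard
heavy-tailed choice for enrichment-domain widths, since no empirical length
distribution is available). Co-localization is injected by anchoring a
fraction *f* of clusters on anchor midpoints with Gaussian jitter (default
sd 200 bp); *f* = 0 is the exchangeable null the Monte-Carlo test assumes,
so calibration checks are exact by construction. EM records are generated
per category so that each satisfies its defining rule exactly at zero
noise (hemicatenane branch fractions are drawn from windows that keep every
pairwise ratio outside the 5% equality tolerance), then degraded with
multiplicative log-normal length noise. qPCR tables invert the
percent-input formula exactly and add Gaussian Ct noise.

What the generator does **not** emulate: tiling-array probe noise and
cluster-calling artifacts, GC or replication-timing biases in binding,
spatially clustered (non-uniform) background placement, correlated
measurement error between EM branches, or qPCR efficiency below 2.0.
Passing tests therefore demonstrate correctness of the statistics under
their own assumptions, not robustness to the systematic structure of real
arrays.

## Numerical and scale choices

Null calibration is checked on 200 independent cluster-set pairs (one 50 kb
chromosome, 15 clusters of log-normal median 400 bp per set, 1000
iterations each): small enough to run in seconds, dense enough (~13%
coverage) that the overlap score is non-degenerate and the achievable
p-values fill (0, 1]. Enrichment recovery uses a 4 × 100 kb genome with 20
anchor features and 25 replicates per anchoring-fraction rung. The
yeast-scale demo (300 clusters, 1000 iterations) runs in ~2 s. All
stochastic stages take an explicit seed and are bit-reproducible given it;
results tables serialize floats at 6 significant digits identically in TSV
and JSON.

## Known limitations

- The Fisher test on base counts ignores autocorrelation; it is reported
  for completeness, never alone.
- The randomization null conditions on one observed pattern; randomizing
  both sets is available but changes the hypothesis being tested.
- The classifier cannot distinguish a hemicatenane whose branch geometry
  coincidentally satisfies the reversed-fork rule (equal pair with a
  shorter complementary branch); rule order resolves ties deterministically
  rather than probabilistically.
- `allow_overlap` randomization shrinks total bases when collisions merge,
  slightly deflating null scores for very dense sets.
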