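# Methods

## The statistic

A comparison takes two labelled ranked lists restricted to their common
label universe of size *n*. Sorting each list ascending puts the most
down-regulated features first; the number of strictly negative
statistics is the *split index*, the zero crossing that separates the
down- and up-regulated halves and delimits the four regulation
quadrants. A value of exactly 0 counts as up-regulated, and ties in the
statistic are broken by label lexicographic order — both are pure
conventions, chosen once so that results are bit-reproducible across
platforms.

For prefix lengths (*i*, *j*) measured from a pair of list extremities,
let *c* be the number of shared labels and *X* ~ Hypergeom(*n*, *i*,
*j*). The one-sided statistic is the enrichment tail P(X ≥ c); the
two-sided statistic is 2·min(P(X ≥ c), P(X ≤ c)) capped at 1, and it is
negatively signed when the lower (depletion) tail attains the minimum.
The one-sided statistic is the enrichment tail itself and is never
negatively signed. Ties between tails (within 1e−12 in log space)
resolve to enrichment. Overlaps below the support minimum
max(0, i + j − n) are clamped to it.

### Log-space evaluation

At transcript scale the tail probabilities underflow double precision
by orders of magnitude, so nothing in the package ever materializes a
raw P-value on the natural scale where it could round to zero: tails
are computed and propagated as natural logarithms. The log-PMF comes
from log-gamma functions; a tail is accumulated with the one-term PMF
recurrence in log space, advancing 24 terms per step through cumulative
sums. Only the *short* tail — the side on which the PMF is decaying —
is summed directly (the other is recovered by complement), so the
accumulation may stop as soon as a geometric bound on the remaining
mass falls 45 nats below the running sum. Support edges are returned as
exactly 0 (P = 1). Natural logarithms are used everywhere; the
customary map display threshold of 3 corresponds to −ln 0.05. Against
exact rational-arithmetic enumeration the worst absolute log error over
all small instances is below 1e−10, and the evaluation stays finite and
accurate in regimes such as n = 200,000, i = j = c = 100,000
(log P ≈ −138,623).

## Counting overlaps

Each list prefix is represented as a bitset — one bit per feature in a
fixed global indexing, packed into 64-bit words. Moving from one
coordinate to a nearby one updates only the bits of features entering
or leaving each prefix, and the intersection count is refreshed from
the bitwise AND of the touched words only. This incremental cursor
serves arbitrary coordinate sequences (coordinates are visited sorted
by (i, j) to bound total movement, and shrinking a prefix is
supported). Two complementary bulk paths exist behind the same module
surface, both cross-checked against naive set intersection and against
the cursor: full lattices (grid search, map rendering) are counted at
once by binning every feature's position pair and taking a 2-D
cumulative sum, and large scattered batches (an EA generation) by a
vectorized dominance count.

## Quadrants

Quadrant bounds follow from the split indices: dd spans
(split_a, split_b), uu the complements, du/ud the mixed products.
Quadrants are searched in their own oriented frames — each quadrant's
pair of extremities is its origin. For the anticorrelated quadrants the
enrichment of the oriented overlap |A-down(i) ∩ B-up(j)| is
algebraically the depletion of the global down–down overlap at the
mapped coordinate (X_dd = i − X_or), so the reported sign is flipped to
−1: quadrant results and the global map tell one story, with
anticorrelation negative. A quadrant with zero extent, or in which no
evaluated coordinate carries the expected sign, is reported
non-significant (log P = 0, empty set) rather than returning the least
bad opposite-direction cell — the sign encodes the direction of effect,
and mixing directions would corrupt the enrichment sets.

The enriched set of a quadrant is the intersection of the two oriented
prefixes at the best coordinate, for all four quadrants. In global map
terms this is, for du/ud, the region between the best coordinate and
the quadrant's outer corner; for perfectly reversed lists the du set is
the entire anticorrelated block, as it should be.

The rendered overlap map is decoupled from the search: both axes run
down→up over the whole lists, cells hold the signed two-sided log P of
the down–down prefix overlap on an evenly spaced lattice (default
200 × 200, the final coordinate always included), and the zero
crossings are recorded for the dashed split lines. Map resolution never
influences numeric results.

## Minimal-P search

**Grid.** The classic strided lattice {s, 2s, …} per axis, always
including the quadrant's far corner; the default stride is
floor(sqrt(n)) (141 for a 20,000-feature analysis). Ties break toward
smaller i, then smaller j. Only the running best is retained.

**Evolutionary algorithm.** Coordinates are individuals; fitness is the
signed log P (wrong-signed coordinates get +∞ but stay in the
population, keeping its size constant). The initial population is
uniformly spaced on the quadrant diagonal, which guarantees — through
elitism — that the result is never worse than a diagonal scan at
population-length resolution. Each generation the distinct coordinates
are ranked, the best fraction (default 0.2) survives, and offspring are
produced by mating two random elites (the child takes i from one
parent and j from the other, either way, or the rounded midpoint of
both — chosen uniformly) followed by mutation: each component
independently receives, with probability 0.5, a signed geometric rank
offset with mean magnitude ≈ quadrant extent / 20, clipped to bounds.
Leaving a component unmutated half the time matters: a law that always
displaces both components can never hand an exact candidate coordinate
to selection, which empirically blocks the final steps of convergence
at transcript scale. The search stops when the elite coordinate set is
unchanged between generations (exact set membership) or after 200
generations. Population defaults to 500 + floor(sqrt(n)), the reading
of the method's published defaults consistent with its stated
O(n^{3/2}) complexity. The search is fully deterministic given its
seed. On planted-overlap instances the EA attains the exhaustively
enumerated global minimum in ≥ 95% of seeded runs and, by
construction, never returns anything worse than its own
initialization's best.

## Adjusted minimal P-values

The minimal coordinate P-value is an extreme statistic over ~n²
strongly dependent tests; it is calibrated against a permutation null.

**Hybrid prediction–permutation (HPP).** When feature-by-sample
log-expression matrices are supplied, features are split into a
*predictor* set (mutually unpredictable) and a *predicted* set. For
every feature the candidate simple regressions on the other features
are ranked by the significance of the slope (t-test, default α = 0.05
unadjusted); among significant candidates the minimal-MSE model is the
best predictor — for simple regressions of a fixed response this is
the maximal |r| model, which is also what the P-value flavour selects
directly. Features with no significant predictor, and
constant-expression features, stay predictors. Prediction chains are
allowed; mutual-best-predictor cycles are broken by moving the
lexicographically smallest label of the cycle into the predictor set.
A null replicate permutes the predictor values and fills in predicted
features in topological order: fold-change flavour logFC_y = β1·logFC_x
(β1 from the expression-level regression), P-value flavour
P_y = |r|·P_x + (1 − |r|)·P̂ with P̂ drawn with replacement from the
original value distribution. With no expression matrices (or no
significant predictors) the scheme degenerates to a plain permutation
of the lists — verified by a two-sample KS test against an explicit
permutation null.

**Null of the minimal P.** R replicates (default 100) of both lists are
drawn, re-ranked, and re-searched with the configured algorithm. The
null statistic is the minimal P-value of the permuted *analysis*: per
replicate, the minimum across the searched quadrants of each quadrant's
overall minimal cell — with no direction filter, because permuted data
carry no direction of effect. Every quadrant's observed (sign-
consistent) minimum is adjusted against that shared null. Two design
properties follow. First, "some quadrant is significant" is a single
family-level event — the global observed minimum crossing the null
threshold — rather than four separate 5% tests (with quadrant-specific
nulls the any-quadrant rate on random backgrounds measures ~9–14%).
Second, the unfiltered null minimum is stochastically lower than any
sign-consistent observed minimum (it may also take wrong-signed
depletion cells), so the threshold is genuinely conservative: the
measured any-quadrant type-I rate on random backgrounds is ~1–3%
against the nominal 5%.

**Beta fit and rescaling.** A beta distribution is fitted to the null
minima by the method of moments (clamping below 1e−300; with mean m and
variance v, k = m(1 − m)/v − 1, α = mk, β = (1 − m)k) and checked with
a Kolmogorov–Smirnov test at the 5% level (composite-hypothesis caveat
acknowledged: the KS test sees the fitted parameters). If accepted, the
threshold is the beta 5% quantile t = CDF⁻¹(0.05); otherwise, or when
the fit is degenerate or more than 10% of the sample clamps, the
empirical 5th percentile. The adjusted value is
min(1, 0.05 · P_min / t), computed in log space so that observed minima
far below underflow remain ordered; a degenerate zero threshold reports
1 with a warning. Because the beta left tail is typically thinner than
the empirical one, the accepted fit is the conservative branch — this,
not the rescaling itself, is where the measured ~1–2% type-I rate
comes from.

## Synthetic data

The generator emulates the canonical study conditions:

* **identical / reversed** — the same list twice, or its negation:
  whole-list concordance, or pure anticorrelation confined to du/ud.
* **four_block** — half the features concordant, half discordant, as
  direction-pure blocks (concordant-down, two discordant blocks of n/4,
  concordant-up) whose ranks interleave evenly within each half of each
  list; the zero crossing sits at a configurable fraction, default two
  fifths. All four quadrants then carry diagonal signals.
* **random** — independent value shuffles; no signal.
* **planted** — the accuracy benchmark: n = 19,962 features with 200
  planted labels placed uniformly at random within the top 300
  down-regulated positions of both lists, everything else randomly
  ranked; a wide preset (1,500–2,500 planted among the top 3,500–4,500)
  is exposed as module constants. Detection is scored on the dd
  enrichment set (TPR over the 200 planted, TNR over the rest,
  accuracy overall).

Values are ranks mapped to a symmetric interval around the zero
crossing; magnitudes are inert for rank statistics. What these data do
not emulate: realistic fold-change distributions, inter-feature
correlation (except through the HPP expression matrices supplied
separately), or noise in the planted positions — so passing benchmarks
demonstrate search optimality and calibration of the statistic, not
robustness to biological noise.

## Problem sizes and numerical choices

The bundled harnesses run, on one CPU, the accuracy benchmark at the
full 19,962-feature geometry (20 replicates; the EA converges in
well under a minute per replicate) and the type-I background with
400 random pairs of 1,000 elements at 100 permutations each (binomial
standard error ≈ 0.56 percentage points at a true rate of 1.3%).
Within the planted benchmark the default-stride grid (stride 141)
lands at coordinate (282, 282); each list's top-282 window captures on
average 94% of the planted positions, so its TPR concentrates around
0.884 with sampling spread ≈ 0.012 — the "up to 11 in 100 missed"
regime — while the EA pinpoints (300, 300) and recovers the planted
set essentially exactly.

Known limitations: the EA inside the permutation loop is expensive
single-threaded (the null is usually run with the grid); the KS
acceptance of the beta fit uses fitted parameters and is therefore
lenient; predictor selection is O(n²) in features unless the candidate
set is capped; and the two-sided statistic "compatible with the
original implementation" of earlier packages is not provided — modes
are exactly one_sided and two_sided.
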