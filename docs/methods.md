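# Methods

This note documents the models and procedures implemented in `coralfate`,
the design choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real annotation data.

## Genet assembly

Patches are nodes keyed by (site, survey year, patch id); temporal links
are undirected edges.  Genets are the connected components
(`networkx.connected_components`), so link direction is irrelevant and
many-to-one/one-to-many link patterns (fusion/fission) need no special
casing.  Genet ids are assigned deterministically — components sorted by
site, first year of appearance, then smallest member patch id — so outputs
are diff-stable across runs.

Validation is strict by default: a link endpoint with no matching patch, a
link joining non-consecutive surveys, and a genet with no patch at an
interior survey between its first and last year are all errors.  The field
workflow links patches only between consecutive surveys, so an interior
gap indicates a broken link table rather than biology.  `strict=False`
downgrades these to warnings and accepts a non-consecutive link as an
explicit, intentional skip over the gap it spans.  A mixed-taxon component
takes its modal member taxon (alphabetical tie-break) and warns, since it
usually reflects an annotation error.

For the quadrat sampling rules, patch diameter is the equivalent-circle
diameter `2·sqrt(area/π)`: polygon geometry is out of scope, and this is
the only diameter computable from the tabular schema.  Quadrats (default
side `sqrt(0.5)` m, i.e. 0.5 m²) are consumed in the given order until 40
genets are selected or 25 quadrats used; any taxon exceeding 100 selected
genets is subsampled to 100 with a configured seed.

## Bleaching rubric

The five-category rubric thresholds the index `I = extent(%) × severity`:
category 1 when `I = 0` or extent < 5 % (a paling floor: trace paling on a
sliver of tissue is "very minor"), 2 for `0 < I ≤ 25`, 3 for `I ≤ 100`,
4 for `I ≤ 200`, 5 above.  The exact bin edges used by field programs are a
judgment call fixed in their scoring diagrams; this table anchors the two
unambiguous corners ((0, ·) → 1 and (100, 3) → 5), is monotone in both
inputs (asserted over the full integer grid at load time), and can be
replaced wholesale by a CSV threshold table, so a program-specific grid
can be dropped in without code changes.

Two genet-scoring methods exist because field protocols describe both: the
default **modal** method assigns the patch category carrying the largest
summed patch area; **aggregate** pools area-weighted extent and
bleached-area-weighted severity across patches and applies the rubric to
the pooled pair (severity pooled over bleached area `area × extent / 100`
because severity describes bleached tissue only, and rounded half-up to
the nearest ordinal level).  Modal ties break toward the higher (worse)
category: for detecting acclimatization — a *decrease* in scores — this is
the conservative direction.  The discrepancy between methods is surfaced
in the output (`method` column), not silently resolved.

For stable genets, "moderate bleaching or higher" is evaluated on the
maximum of the two event-year categories: a genet that reached category 3
in either event demonstrably bleaches under this level of heat stress, so
it cannot be called thermally tolerant.  The 5×5 decision table is emitted
and checked exhaustively by a test.

## Bootstrap acclimatization test

Per population, `n` observed changes are resampled with replacement `B`
times (default 100,000); `p = #{median ≥ 0}/B`.  The `≥ 0` rule is
inclusive exactly as specified, which makes the test conservative: with a
discrete, often zero-inflated change distribution, resample medians tie at
0 frequently and count against acclimatization.  The median of an
even-length resample is the mean of the middle two order statistics (the
standard definition; nothing in the procedure depends on another choice).
Populations with fewer than 10 surviving genets are reported ineligible
with no p-value, never as a division by zero.

Each population draws from its own RNG stream seeded by the master seed
plus a CRC-32 hash of (site, taxon), so a population's p-value does not
depend on how many other populations were tested first.  No
multiple-testing correction is applied across populations (the Bonferroni
correction belongs to the pairwise Fisher family); callers can adjust the
returned p-values if they wish.

`enumerate_exact_p` computes the same probability exactly by enumerating
resample multisets with multinomial weights (feasible to n = 8) and is the
oracle the bootstrap is tested against: 50 random vectors with n ≤ 5 agree
within 0.01 at 100,000 resamples, and 1,000 symmetric-null populations of
n = 50 reject at a rate within [0, 0.10] at α = 0.05.

## Fisher tests, Bonferroni, letters

2×2 tables use full hypergeometric enumeration with exact integer weights
`C(r₁, x)·C(r₂, c₁−x)`, so the two-sided inclusion rule (tables no more
probable than observed) is decided without floating-point ambiguity.
Larger tables are enumerated exactly while the margin-constrained table
space holds ≤ 10⁶ tables; beyond that a seeded Monte-Carlo sample of
100,000 tables from the margins is used and flagged in the result.  The
Bonferroni family for pairwise site comparisons is all `C(k, 2)` pairs
within one taxon.

The compact letter display uses the insert-and-absorb construction: start
with one letter covering all groups; for each significant pair, split
every letter set containing both into two sets each missing one member;
absorb subsets.  The letter count is not guaranteed minimal, but the
defining invariant — two groups share a letter iff they are not
significantly different — is re-verified programmatically on every emitted
display.

## Logistic models

Bleaching (binarized at category ≥ 3) and survivorship are modelled by
logistic regression fitted with iteratively reweighted least squares
(convergence at max coefficient update < 1e-8, cap 100 sweeps).  The
deviance path is retained and is non-increasing.  Quasi-complete
separation is flagged when a coefficient exceeds 15 on the logit scale
while the deviance is still improving; Wald p-values are withheld in that
case.  Rank-deficient designs are rejected naming the collinear columns.
The size covariate enters as natural-log planar area in both models
(consistent with the log transformation used for the growth analysis; the
design helper can be fed raw area if preferred).

The survivorship model uses treatment coding with the alphabetically first
site as reference, site main effects and site × ln(area) interactions.
Pairwise site contrasts are Wald tests on main-effect coefficient
differences, Bonferroni-adjusted, restricted to sites whose interaction
term is non-significant at α = 0.05 (a site whose size slope differs has
no single "site effect" to compare); the reference site carries no
interaction term and is always eligible — a caveat of treatment coding
worth remembering when reading the contrasts.

## ANCOVA and diagnostics

Growth is modelled as `ln(final area) ~ ln(initial area) + factor`
(optionally + interaction), with factor levels below 10 observations
dropped before fitting.  Per-term F statistics come from covariate-first
sequential sums of squares computed from explicit nested model fits, so
the factor is always tested after adjusting for initial size.  (Generic
ANOVA-table helpers can order the categorical term first, which silently
tests the factor *unadjusted*; the nested-fit construction avoids that
trap, and a 1,000-replicate null simulation confirms the factor type-I
rate sits in [0.02, 0.08] at α = 0.05.)

Residual diagnostics are the Shapiro–Wilk test for normality and Cochran's
`C = max(s²ᵢ)/Σ s²ᵢ` for homogeneity of variance across factor groups,
with the classical critical-value approximation inverted into a p-value:
`F = (k−1)·C/(1−C)` referred to `F(ν, ν(k−1))` with a Bonferroni factor
`k`, `ν = n̄ − 1` using the mean group size for unbalanced data.  Constant
residuals are flagged rather than tested.

## Synthetic community generator

The generator inverts the observational direction of the analysis:
phenotypes (tolerant / decreased / increased / susceptible) are assigned
a priori per genet and drive the event-year category draws, which is what
makes classification testable against ground truth.  Category pairs are
drawn from per-phenotype admissible sets (e.g. decreased requires
`c₁ ≥ c₂ + 2`); extent/severity values are then drawn uniformly inside the
rubric band of the target category, identically for all patches of the
genet, so the modal genet score equals the drawn category by construction.

Default parameters describe the study conditions the analysis was designed
around: five surveys (2014, 2015, 2017, 2019, 2021) with events in 2015
and 2019; six sites; four taxa totalling 305 genets per site (1,830
overall).  Per-taxon settings encode the qualitative structure of a
leeward-Maui-like community:

| taxon (per site n) | phenotype mix (tol/dec/inc/sus) | survival logit per interval |
|---|---|---|
| *Montipora capitata* (65)  | .25/.10/.10/.55 | 0.41 + 0.35·ln A |
| *Montipora patula* (60)    | .78/.06/.10/.06 | 0.31 + 0.35·ln A |
| *Pocillopora* spp. (40)    | .15/.20/.10/.55 | 1.93 − 0.35·ln A |
| *Porites lobata* (140)     | .35/.30/.10/.25 | 0.51 + 0.40·ln A |

Survival intercepts were set so that four intervals at the median colony
size (ln A ≈ 4, initial sizes lognormal(4, 1.2) cm²) yield end-to-end
survivorship near 55 %, 51 %, 16 % and 63 % respectively — the
Pocillopora-like taxon loses most genets and is the only one whose
survival declines with size.  Growth is a lognormal multiplier
(μ = 0.05, σ = 0.3) per patch per interval.  Fission (p = 0.15 per
interval, split fraction uniform in [0.2, 0.8]) and fusion (p = 0.3 while
fragmented) operate at a single level — a genet is one or two patches —
which is the simplest structure that still exercises the temporal graph
code; nested fragment trees are not modelled.  Paling noise (p = 0.005 per
event year) shifts a drawn category up one step and is the only source of
phenotype-classification error; non-event years get sub-threshold paling
with the same probability.

`null_scenario` symmetrizes every phenotype's category-pair distribution
under event swap (redistributing directional mass between the decreased
and increased buckets), making the change statistic symmetric about 0 for
type-I calibration; the operation is idempotent.

**What the generator does not emulate:** spatially structured quadrat
geometry (centroids are uniform), recruitment, time-varying or
patch-level mortality (survival acts on whole genets with one
per-interval coefficient pair per taxon), environmental covariates (DHW
enters only as scenario narrative), annotation error in areas, and
inter-annual correlation of bleaching beyond the phenotype.  Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated model, not robustness to every failure mode of field
annotations.

## Determinism and problem sizes

All randomness flows from explicit seeds: the generator uses
`SeedSequence` substreams per genet, the bootstrap one stream per
population, Monte-Carlo Fisher a caller-supplied seed.  The pipeline is a
pure function of (inputs, configuration, seed); CSV floats are written
with `%.10g` and JSON keys sorted, so report bundles are byte-identical
across runs and the golden-file test pins the packaged fixture
(three sites, 240 genets, seed 42, 20,000 resamples).  Test simulations
use 100-replicate recovery studies and 1,000-replicate calibration runs,
sizes at which binomial noise on the asserted rates is comfortably inside
the asserted bands.

## Known limitations

- Fisher r×c exactness falls back to Monte Carlo for large tables; the
  p-value then carries ~0.001–0.003 simulation error.
- Cochran's p uses the classical F approximation; for very unbalanced
  groups it is approximate.
- The bootstrap p is right-inclusive by definition and cannot detect
  *increasing* bleaching (that is read from the response classes instead).
- Compact letter displays are correct but not guaranteed minimal in the
  number of letters.
- Pairwise survivorship contrasts inherit the reference-site asymmetry of
  treatment coding described above.
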