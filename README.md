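# coralfate

Fate tracking of clonal corals through repeated marine heatwaves.

`coralfate` is a Python toolkit for analysing multi-year coral reef
annotation tables (one row per contiguous live-tissue *patch* per survey,
plus patch-to-patch temporal links) in which colonies split by partial
mortality (fission) and regrow together (fusion).  It is aimed at reef
ecologists working with orthomosaic-derived tracings who want to ask: do
individual corals, and coral populations, bleach less under a second heat
stress of similar magnitude — and does bleaching history predict growth and
survival?

## The model

**Genets.** Patches linked across consecutive surveys form a temporal
graph; each connected component is a *genet* (a putative genetic
individual).  A genet's planar area in a year is the sum of its member
patch areas; it survives the timeseries if it holds at least one patch in
both the first and the final survey.  Analyses use the cohort of genets
alive at the first survey.

**Bleaching score.** Every patch carries a bleaching extent `E` (% of area
paled, 0–100) and severity `S` (ordinal 0–3 scored on the bleached tissue
only).  A monotone rubric on the index `I = E·S` maps each patch to one of
five categories (1 = none/very minor paling … 5 = extreme).  A genet's
category in a year is the area-weighted modal patch category (an aggregate
method that pools area-weighted extent and bleached-area-weighted severity
first is also available).

**Change statistic and response classes.** With event-year categories
`c₁` (2015) and `c₂` (2019), the per-genet change is `Δ = c₂ − c₁ ∈ [−4, 4]`.
Genets with `Δ ≤ −2` decreased their bleaching response (consistent with
acclimatization), `Δ ≥ +2` increased it; stable genets (|Δ| ≤ 1) are
*highly susceptible* if they reached moderate bleaching (category ≥ 3) in
either event and *thermally tolerant* otherwise.

**Acclimatization test.** For each population (taxon × site), the vector of
`Δ` over genets alive in both events is bootstrapped (100,000 resamples
with replacement); the one-sided p-value is the proportion of resample
medians ≥ 0, at α = 0.05, requiring ≥ 10 surviving genets.

**Population statistics.** Pairwise Fisher's exact tests on response-class
contingency tables with Bonferroni correction and a compact letter display;
logistic regressions of bleaching (category ≥ 3) and of survivorship on
ln planar area (survivorship with site × size interactions and pairwise
Wald contrasts between non-interacting sites); ANCOVA of ln final area on
ln initial area plus bleaching response (covariate-first sequential sums of
squares) with Shapiro normality and Cochran variance-homogeneity
diagnostics.

A synthetic community generator (`coralfate.simulate`) produces patch/link
tables with known per-genet phenotypes, size-dependent survival, growth and
fission/fusion, so every stage can be validated against ground truth.

## Worked example

```python
from coralfate.simulate import SimConfig, simulate_community
from coralfate.io import RunConfig, run_pipeline

patches, links, truth = simulate_community(SimConfig(seed=42))
results = run_pipeline(
    RunConfig(out_dir="out", seed=42, n_resamples=100_000),
    patches=patches, links=links,
)
acclim = results["acclim_results"]
print(acclim[acclim.taxon == "Porites lobata"].to_string(index=False))
```

prints (abridged):

```
     site          taxon   n  eligible  observed_median       p  n_resamples
 Kahekili Porites lobata  90      True              0.0 0.99335       100000
  Olowalu Porites lobata 108      True              0.0 0.68651       100000
Ukumehame Porites lobata 103      True              0.0 0.68748       100000
```

Each row is one population: `n` surviving genets carried a bleaching score
in both events, the observed median change is 0 (most genets held the same
category in 2015 and 2019), and `p` is the bootstrap probability of a
resample median ≥ 0 — far from the α = 0.05 threshold, so these simulated
populations show no population-scale acclimatization even though
individual genets with decreased responses exist.  Per-taxon survivorship
from the same run (`results["genets"].groupby("taxon").survived.mean()`):

```
Montipora capitata    0.577
Montipora patula      0.514
Pocillopora spp       0.154
Porites lobata        0.652
```

The Pocillopora-like taxon loses most genets (its survival declines with
colony size), while massive taxa survive at 50–65 %.

The same pipeline runs from the shell:

```bash
coralfate simulate --seed 42 --out-dir sim
coralfate run sim/patches.csv sim/links.csv --out-dir out --seed 42
```

## Documentation

See `docs/methods.md` for the statistical methods, generator design,
numerical choices and known limitations.
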