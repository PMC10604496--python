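# Methods

## Model and cost function

Panel reduction is cast as minimization over the `2^k` subsets of `k`
codominant loci.  The cost of a panel is the relative deviation of its
average genetic distance (AGD) from the full-panel AGD, in percent.  The
between-group distance is Nei's standard genetic distance computed from
observed allele frequencies, with the locus sums accumulated inside the
ratio before the logarithm — not a per-locus average of ratios.  Groups are
subpopulations when the dataset carries at least two population labels;
otherwise each diploid individual is a group (its frequency vector lies in
{0, ½, 1}).  Both modes are selectable (`grouping=`), with `auto` picking
the population mode when possible.

Degenerate cases are handled explicitly rather than smoothed over:

* a pair of groups sharing no alleles on the panel gets an **infinite**
  distance, which is flagged and excluded from the AGD (never capped —
  capping would distort the cost ordering);
* loci with no observed genotypes on one side of a pair are excluded from
  that pair's sums, with the count reported;
* a panel whose AGD is undefined (every pair infinite or data-free) scores
  infinite loss, so the optimizer discards it naturally;
* panels below two loci are rejected by the cost function, and the
  degenerate margin `0` returns the full panel with a warning.

Missing data follow a whole-genotype rule: a genotype is missing when
either allele code is 0, and missing genotypes leave both numerator and
denominator of every per-locus statistic (frequencies therefore come from
observed calls only, with per-locus denominators).  Allele codes are opaque
integers; no statistic or distance depends on their values, only on
identity — a property the test suite checks by relabeling.

## Per-locus statistics

* `Na`: distinct observed alleles (pooled).
* `Nea = 1 / Σp²` on pooled frequencies.
* `He = 1 − Σp²` (no small-sample correction by default; the `2n/(2n−1)`
  correction sits behind `bias_corrected=`, since the plain form is what
  the rest of the pipeline consumes).
* `Ho`: fraction of observed genotypes with two distinct alleles.
* `PIC` in the Botstein form `1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`, the standard
  codominant-marker definition; one formula is used everywhere.
* `AR = Na / total individuals in the dataset` — a ratio convention, not
  rarefaction-based richness (rarefaction is out of scope).  A structural
  consequence worth knowing: per-panel fold changes of `AR` and `Na` are
  identical, which the evaluation module uses as a consistency check.

Whether `AR` should be pooled or per-population-averaged was an open
choice; pooled is used.

## Ant colony search

The search space is a graph with two pheromone-carrying edges per locus
(include / exclude).  Defaults follow the published parameterization for
this problem: 50 ants per epoch, 120 epochs, pheromone weight `α = 0.7`,
retention `decay = 0.9`.  `decay` is interpreted as **retention**
(`τ ← 0.9·τ` per epoch): the alternative reading (10 % retained) empties
the trails almost immediately and contradicts the role of a small decay as
an exploration device, so retention semantics are documented prominently.

Construction modes:

* **fixed-N**: `N` loci drawn sequentially without replacement with
  probability ∝ `τ_inc^α` among the remaining loci (implemented exactly as
  the Gumbel-top-N equivalent of sequential weighted sampling);
* **free**: each locus included independently with probability
  `τ_inc^α / (τ_inc^α + τ_exc^α)`; panels below two loci are resampled a
  bounded number of times and then topped up deterministically by pheromone
  rank.

There is deliberately no separate heuristic-desirability exponent (no `β`
term): locus informativeness enters only through pheromone initialization.
Random initialization draws every edge from `Uniform(ε, 1)` with
`ε = 0.01`; PIC seeding sets `τ_inc = ε + PIC`, `τ_exc = ε + (1 − PIC)`.

**Update rule.**  After each epoch the trails evaporate (`τ ← decay·τ`,
floored at `ε` so they stay strictly positive), the epoch's panels are
ranked by loss (ties: smaller panel, then lexicographic locus order),
duplicates are removed — a panel built by several ants carries no extra
information — and each of the top `⌈elite_fraction · ant_n⌉` distinct
panels deposits

```
Δ = (100 − loss)/100 · (1 − decay)/n_elite
```

on the edges of its own tour.  The `(1 − decay)/n_elite` factor makes the
update an exponential moving average: trails stay on the `[ε, ~1]` scale of
their initialization instead of accumulating without bound.  This matters.
With unscaled quality deposits the trails of early favorites grow to the
order of `1/(1 − decay)` over a fixed `ε` floor, the colony converges by
roughly epoch ten, and the remaining hundred epochs explore nothing; in
that regime the search matched the enumerated optimum on only ~80 % of
small instances.  With the EMA scaling, deduplicated elites, plus a
**stagnation restart** (trails re-initialized after `stagnation = 25`
epochs without a global-best improvement, a standard colony-restart
device), the fixed-size search matches the exhaustive optimum on 19–20 of
20 default-configuration runs for `k = 12` instances, for both random and
PIC initialization.

The global best is tracked across epochs with deterministic tie-breaking
(loss, then panel size, then lexicographic locus order), so runs are fully
reproducible given a seed, and the per-epoch best-loss trace is
non-increasing by construction.

**Margin mode** follows a progressive-reduction schedule: run the fixed-N
search for `N = k−1` down to 2, keep the last panel within the margin, stop
at the first `N` whose best-found loss exceeds it, and fall back to the
full set if even `k−1` loci fail.  The deterministic PIC-rank scheme scans
upward from `N = 2` instead (cheapest first); both return the minimal
qualifying size, so results are comparable.  The PIC+ACO scheme does not
force-include the top-PIC locus — seeding is a soft bias, because highly
informative loci can still be redundant given the rest of a panel — but an
optional `force_top` flag pins it for users who want the hard rule.

An exhaustive enumerator (`exhaustive_optimum`, guarded at `k ≤ 20`) serves
as the independent oracle in tests; the ant colony is never validated
against itself.

## Scheme comparison and panel evaluation

`compare_schemes` races the schemes across panel sizes; stochastic schemes
contribute seeded replicates (default 20, configurable — the appropriate
replicate count is study-dependent), deterministic ones a single value.
Accuracy is defined as `100 − loss`.  Pairwise contrasts per size use Tukey's
honest significant difference test via statsmodels; the degenerate
zero-variance case (schemes returning identical accuracies) is reported as
exact-tie contrasts with `p = 1` rather than NaN.

`panel_discrepancy` compares the per-locus statistic values of the reduced
panel against the full set with a two-sample t-test — Student's
pooled-variance form by default, Welch behind a flag — and reports absolute
mean difference, fold change (reduced/full) and a significance tier:
`ns` (p > 0.05), `slight` (0.01 < p ≤ 0.05), `moderate` (0.001 < p ≤ 0.01),
`high` (p ≤ 0.001).  Note the reduced panel is a subset of the full set, so
the two samples are not independent; the tier is a descriptive effect-size
gauge, exactly as such report tables use it, not a confirmatory test.  The
degenerate full-set "panel" yields a row of NaNs with tier `na`.

## Synthetic data

`simulate_genotypes` draws Fst-structured diploid tables under the
Balding–Nichols construction: per locus, ancestral frequencies from a
symmetric Dirichlet (concentration 1.0 by default — a flat prior over the
simplex); subpopulation frequencies from `Dirichlet(ancestral · (1−Fst)/Fst)`;
genotypes under Hardy–Weinberg within populations; whole genotypes masked
to missing at a configurable rate.  Defaults (4 populations × 30
individuals, 12 loci, 5–20 alleles per locus, Fst 0.15, 2 % missing) are a
desk-scale analogue of real multi-population microsatellite surveys — tens
of individuals per population, multi-allelic loci, moderate structure —
sized so exhaustive enumeration stays feasible as an oracle.  What the
generator does **not** emulate: genotyping error and allele dropout,
linkage between loci, mutation-model (stepwise) allele spacing, and
real-data departures from Hardy–Weinberg within populations.  Passing
tests therefore certify the optimizer and statistics machinery, not the
biology of any particular dataset.

`make_planted_instance` builds the benchmark with a known optimum.  Design
constraint worth recording: with the ratio-form distance, undifferentiated
"noise" loci with non-negligible `Σp²` pull every pairwise distance toward
zero, so the best small panel under the AGD-matching cost is then a
signal/noise *mixture* — a fully generic noise construction cannot make the
differentiated loci the optimum.  The generator therefore makes the filler
loci **patchily genotyped** (observed in a single population only, the
amplification-failure pattern real panels exhibit): the pairwise no-data
rule excludes them from every population pair, the signal panel reproduces
the full AGD exactly (loss 0 by construction), and any smaller panel
misses by a wide margin.  The signal loci use an 8-allele pool split
between two population "sides", with a heterogeneous divergence profile
(one locus at `separation`, the rest near `0.3 · separation`) chosen by
maximizing the analytic worst-case sub-panel mismatch — about 20 % of the
AGD for the default `n_best = 4`, and at least ~9 % empirically across
seeds, comfortably above the 5 % margin used in tests.  Filler loci are
skewed biallelic where observed, so their PIC (≈ 0.05–0.3) sits well below
the signal loci (≈ 0.86) and PIC seeding genuinely points at the planted
panel.  Locus columns are shuffled so position encodes nothing.

## Numerical choices

* Frequencies are exact ratios of integer counts; simplex sums are checked
  to 1e-12 in tests.
* Distances with `|D| < 1e-12` are snapped to 0 to absorb round-off in the
  identical-groups case.
* Oracle/ACO loss comparisons use an absolute 1e-9 tolerance.
* All randomness flows through `numpy.random.Generator`; one user seed is
  expanded into per-component child seeds via `SeedSequence.spawn`, so
  replicates are individually reproducible.
* Tie-breaks (panel ranking, PIC ranking) are deterministic: loss, then
  size, then lexicographic order; PIC ties by locus position.

## Known limitations

* The AGD cost is blind to within-population heterozygosity, so a panel
  that preserves between-population distances can still bias inbreeding-
  related quantities; the discrepancy report exists to surface exactly that.
* Margin mode's early stop assumes best-found loss grows as panels shrink;
  on near-degenerate data a smaller qualifying panel past the first failure
  would be missed (the exhaustive enumerator is the recourse at small `k`).
* `AR` is a sample-size-bound ratio, not rarefied richness; values are only
  comparable within a dataset.
* No Fst/chord/Jost distance families, no genetic-algorithm or
  particle-swarm baselines, no external population-structure software
  integration.
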