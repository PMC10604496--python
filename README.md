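# msatpanel

Reduced microsatellite marker panels that preserve average genetic distance,
selected by ant colony optimization seeded with polymorphic information
content (PIC).

## The problem

Microsatellite (SSR) genotyping panels used in genetic diversity surveys,
breeding programs and conservation monitoring often carry 10–30 loci, and
every locus costs primers, PCR lanes and scoring time.  Most panels are
redundant: a well-chosen subset estimates the same population-genetic
quantities within a stated error margin.  `msatpanel` treats panel reduction
as combinatorial optimization.  A candidate panel is a binary inclusion
vector `I = [i_1 … i_k]` over the `k` loci; its cost is how far it moves the
**average genetic distance (AGD)** between the study's populations away from
the full-panel value:

```
D_ab(I)  = −ln [ Σ_k Σ_j p_ajk p_bjk / sqrt( Σ_k Σ_j p_ajk² · Σ_k Σ_j p_bjk² ) ]
AGD(I)   = mean over population pairs (a, b) of D_ab(I)
loss(I)  = 100 · |AGD(I) − AGD(full)| / AGD(full)      [percent]
```

where `p_ajk` is the frequency of allele `j` at locus `k` in population `a`
(Nei's standard genetic distance, with the locus sums inside the ratio, over
included loci only).  Datasets with a single population are handled by
treating each diploid individual as a group with allele "frequencies" in
{0, ½, 1}.

Four selection schemes share one interface:

| scheme    | how it picks loci                                              |
|-----------|----------------------------------------------------------------|
| `PIC`     | rank loci by PIC, keep the top of the list (deterministic)      |
| `ACO`     | ant colony search over include/exclude trails, random start     |
| `PIC+ACO` | ant colony search with trails seeded from per-locus PIC         |
| `RANDOM`  | uniform random panel (control)                                  |

The ant colony walks a graph with two nodes per locus (include/exclude).
Per epoch, 50 ants construct panels from the pheromone trails (weight
`τ^α`, α = 0.7), the best-ranked distinct panels deposit pheromone
proportional to solution quality, and trails retain a 0.9 fraction per
epoch.  PIC seeding (`τ_inc = ε + PIC`, `τ_exc = ε + (1 − PIC)`) starts the
search at informative loci, which measurably cuts the epochs needed to
reach the optimum.  Searches run either at a fixed panel size `N` or in
margin mode, which shrinks `N` stepwise and returns the smallest panel whose
loss stays within the margin.

Per-locus statistics (`Na`, effective alleles `Nea = 1/Σp²`, allele richness
`AR = Na / individuals`, `Ho`, `He = 1 − Σp²`, and Botstein PIC
`1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`) serve both as the seeding signal and as
evaluation metrics: the package reports how a reduced panel biases each
statistic (two-sample t-test with significance tiers) and races the schemes
against each other with Tukey HSD contrasts.

## Worked example

Genotypes travel in the GenAlEx codominant layout (two columns per locus,
allele code 0 = missing) or an equivalent wide CSV; a built-in simulator
generates Fst-structured multi-allelic datasets so everything runs without
external data:

```bash
msatpanel simulate --seed 42 --n-pops 4 --n-per-pop 30 --n-loci 12 --out sim
msatpanel stats sim/genotypes.txt --out stats
msatpanel select sim/genotypes.txt --scheme pic-aco --margin 5 --seed 7 --out sel
msatpanel evaluate sim/genotypes.txt --panel sel/panel.txt --out ev
```

The `stats` table starts:

```
locus   Na   Nea      AR        PIC       Ho        He
L01     5    3.46952  0.041667  0.673173  0.641026  0.711776
L02     12   8.7122   0.1       0.874413  0.758621  0.885218
```

and `select` prints

```
PIC+ACO: 2 loci, loss 0.5053%
```

meaning the search found a 2-locus panel (`L04`, `L08`) whose AGD deviates
from the 12-locus AGD by 0.51 % — inside the requested 5 % margin.  On this
deliberately homogeneous simulated dataset two informative loci already
reproduce the between-population distances; real panels with heterogeneous
loci retain more markers (the margin run reports, per size, the best panel
found before the loss margin is exceeded).  The `evaluate` report then
shows the reduced panel's per-locus statistics against the full set, e.g.
`Na` fold change 1.09 with `p = 0.73` (tier `ns`): this 2-locus panel does
not significantly bias the diversity metrics.

The same operations are available as a library, shaped like scikit-learn
feature selectors:

```python
from msatpanel import PICACOSelector, read_genalex

G = read_genalex("sim/genotypes.txt")
sel = PICACOSelector(margin=5.0, seed=7).fit(G)
sel.panel_.included   # ['L04', 'L08']
sel.loss_             # 0.505…
reduced = sel.transform(G)   # GenotypeMatrix restricted to the panel
```

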