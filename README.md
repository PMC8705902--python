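# gutflux

Diet-constrained community metabolic modelling of the gut microbiome.

Longitudinal nutrition interventions change which microbes dominate the gut
and, through them, which metabolites the community can secrete. Measuring
those metabolites directly is hard; predicting them from metagenome-derived
strain abundances and curated genome-scale metabolic models (GEMs) is not.
`gutflux` implements that prediction pipeline for researchers who have
per-sample strain relative abundances, strain-level metabolic models, a
quantified diet, and clinical time series, and who want to know **which
metabolites the community can secrete, which strains produce them, and
which of them track the host's phenotype**.

## What it computes

For each sample the package builds a multi-compartment community model:
every retained strain (relative abundance ≥ 0.1% by default, renormalised)
is tagged into its own compartment and connected to a shared lumen pool
`[u]` through per-strain `IEX` transports; the lumen exchanges with a diet
inflow layer `[d]` and a fecal outflow layer `[fe]`. An abundance-weighted
community biomass reaction (coefficients = abundances `a_k`) drains each
strain's biomass species, and every strain reaction is flux-coupled to its
own biomass,

```
|v| ≤ c · v_biomass + u        (defaults c = 400, u = 0.01)
```

so organisms cannot carry flux out of proportion to their growth. Under a
diet flux vector (mmol/day, applied as `lb(EX_m[d]) = −flux`), flux
variability analysis (FVA, holding the community biomass at a fraction
γ = 0.9999 of its optimum) gives per metabolite the four exchange
primitives, combined as

```
net_secretion(m) = maxFlux(EX_m[fe]) + minFlux(EX_m[d])
net_uptake(m)    = |minFlux(EX_m[d])| + minFlux(EX_m[fe])
```

Metabolites are classified (secreted-only / uptake-only / both / inert),
summed by metabolism subsystem, and attributed to strains via FVA of each
strain's `IEX` flux (share = positive maximum over the sum of positive
maxima). Net-secretion series are then screened against clinical series
(BMI, leptin, adiponectin, the leptin/adiponectin ratio, ...) with Spearman
rank correlation, Benjamini–Hochberg FDR over the full pair family, and the
thresholds |ρ| > 0.7, FDR p < 0.1, yielding a tri-partite
clinical–metabolite–strain network (GraphML export).

A first-class synthetic-data module generates small chain-topology strain
models, abundance/diet/clinical scenarios with planted producers and
rank-exact planted correlations, and closed-form expected answers — every
stage is testable without any external model collection.

## Worked example

```
$ gutflux synth --seed 1 --out demo
$ cd demo && gutflux run-all --scenario-dir . --out results
```

`net_fluxes.tsv` (mmol/day; uptake fluxes signed):

```
sample  metabolite  max_secretion  min_secretion  max_uptake  min_uptake  net_secretion  net_uptake
day0    3mop        100.06         0              0           0           100.06         0
day0    fol         20.02          0              0           0           20.02          0
day0    fol_pre     200            0              -200        0           0              200
```

The planted folate-like producer ramps from 5% to 25% abundance over the
seven timepoints, and because the flux-coupling cap `c·a_k·μ + u` is the
binding constraint, folate net secretion rises accordingly
(20.02 → 100.06 mmol/day) while the declining producer's ketoacid falls
symmetrically. `edges.tsv` recovers the planted clinical structure:

```
metabolite  clinical             rho        p_raw       p_fdr       sign
fol         BMI                  -0.892857  0.00680719  0.00850898  -
fol         adiponectin          0.892857   0.00680719  0.00850898  +
fol         leptin/adiponectin   -0.928571  0.00251947  0.00850898  -
3mop        BMI                  0.892857   0.00680719  0.00850898  +
...
```

i.e. the folate-like metabolite correlates negatively with BMI at
ρ = −0.89 (raw p = 0.0068 from the t approximation at n = 7), survives the
FDR screen, and `contributions.tsv` attributes 100% of its production to
the planted producer strain. `network.graphml` contains the corresponding
clinical–metabolite–strain graph, and `diversity.tsv` reports the Shannon
index of each filtered profile.

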