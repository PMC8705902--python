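# Methods

## Constraint-based model

A metabolic model is a set of metabolites (keyed by id and compartment), a
set of bounded reactions with real stoichiometric coefficients, and an
objective. Flux balance analysis (FBA) solves

```
max / min   c·v
s.t.        S v = 0,   lb ≤ v ≤ ub,   couplings
```

with HiGHS through `scipy.optimize.linprog`. Flux variability analysis
(FVA) minimises and maximises each requested reaction flux under the same
constraints, optionally with the extra row `objective ≥ γ · FBA-optimum`.
Solver infeasibility and unboundedness are surfaced as explicit statuses or
errors, never as silent zeros. Feasibility and optimality are interpreted
at an absolute flux tolerance of 1e-6; tests assert mass balance
`‖S v‖∞ ≤ 1e-6` on every optimal solution.

Coupling constraints are pairs of inequality rows

```
 v_r − c · v_anchor ≤ u
−v_r − c · v_anchor ≤ u
```

confining `|v_r|` to `c · v_anchor + u`. The anchor is a biomass reaction;
in a community this prevents flux through organisms that do not grow.
Defaults `c = 400`, `u = 0.01` follow the convention of the community
modelling toolboxes this layout is compatible with; both are configurable
per run, as is γ (default 0.9999 — close enough to the optimum to pin
community growth while leaving numerical slack; γ = 0 reproduces
unconstrained variability studies).

## Community construction

Per sample, strains below the abundance cutoff τ (default 0.001, i.e.
0.1%) are removed **before** renormalisation; strains exactly at τ are
retained; the survivors are rescaled to unit sum. An all-below-cutoff
profile is an error ("empty community"), not an empty model.

Each retained strain model is rewritten for membership: reaction ids gain a
`<strain>_` prefix, the extracellular compartment becomes `c_<strain>`
(other compartments `<strain>_<tag>`, which avoids a collision when a
model's cytosol tag is literally `c`), and every formerly exchanged
metabolite gets a reversible `<strain>_IEX_<m>[u]tr` transport into the
shared lumen, oriented so positive flux is secretion. Strain-level exchange
reactions are removed — the lumen/diet/fecal layers replace them. Products
of the biomass reaction are deliberately kept private (no IEX): routing
biomass through the fecal drain would let a strain grow outside the
abundance-weighted community biomass and inflate its coupling cap.

For every lumen metabolite the community gains the quartet `EX_m[d]`
(diet exchange, closed until a diet is applied), `DUt_m` (diet→lumen),
`UFEt_m` (lumen→fecal) and `EX_m[fe]` (fecal exchange, open above 0). The
community biomass reaction consumes each strain's biomass species at its
abundance (`Σ_k a_k · biomass_k → microbeBiomass[u]`), flows to a fecal
exchange that serves as the objective, and is bounded to [0.4, 1.0] per day
by default (configurable; property tests that compare a one-strain
community against the bare strain model open these bounds). Strain models
keep their native per-gDW-per-hour bounds; the community exchange layer is
interpreted in mmol/day and this unit convention is recorded as model
metadata rather than applied as a hidden conversion.

Applying a diet sets `lb(EX_m[d]) = −flux_m, ub = 0` for each diet
metabolite with a lumen counterpart (entries without one are skipped with a
warning), closes all other diet exchanges, and optionally opens a trace
allowance ε (default 0.1 mmol/day) for metabolites on a configured
essential-micronutrient list — the mechanism that makes database-derived
diets growth-feasible when a model requires an ion the menu does not list.

## Net fluxes, roles, attribution

The per-metabolite FVA primitives are max/min fecal secretion (flux of
`EX_m[fe]`, ≥ 0) and max/min diet uptake (flux of `EX_m[d]`, ≤ 0; the
minimum is the strongest draw). The verbal definition "net secretion = max
secretion + minimal uptake" is sign-ambiguous, so the package fixes

```
net_secretion = maxFlux(EX_m[fe]) + minFlux(EX_m[d])
net_uptake    = |minFlux(EX_m[d])| + minFlux(EX_m[fe])
```

and always emits all four primitives so the alternative reading can be
reconstructed from the output table. Role classification is per metabolite
across samples at tolerance 1e-6: net secretion above tolerance in any
sample and/or net uptake above tolerance give secreted-only / uptake-only /
both; neither gives inert; the four classes partition the metabolite
universe by construction. Subsystem summaries sum positive net secretion by
the metabolites' subsystem labels (unmapped → "other", logged).

Strain attribution runs the same γ-constrained FVA over each strain's IEX
flux for a metabolite; the share is the strain's positive maximum over the
sum of positive maxima (non-producers contribute nothing and shares lie in
[0, 1] and sum to 1 when any producer exists). Shannon diversity
`H = −Σ a ln a` (natural log) is computed on the filtered, renormalised
profile.

## Diet construction

Food-intake records (grams/day per food and period, multiple formula rows
summed) combine with a user-supplied nutrient-composition table (mass
fraction of metabolite per gram of food) and molar masses:

```
flux_m = Σ_food  g/day · fraction(food, m) / MW_m · 1000    [mmol/day]
```

Nutrients map to lumen metabolites by exact id; there is no fuzzy matching.
The composition table is the extension point for foods absent from public
databases and also carries the responsibility for what fraction of each
food escapes host digestion — the packaged toy compositions document their
assumption explicitly.

## Correlation screen and network

Spearman ρ is the Pearson correlation of average ranks (equal to
`1 − 6Σd²/(n(n²−1))` for tie-free data). The default two-sided p-value uses
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom, which reproduces the
familiar p ≈ 0.0068 at ρ = 0.8929, n = 7; |ρ| = 1 is reported as p = 0
with a flag. An exact permutation option enumerates all n! permutations for
n ≤ 9 (5040 at n = 7). All metabolite × clinical pairs form one FDR family
(Benjamini–Hochberg step-up, via statsmodels, verified against the
definition); constant series are skipped with a warning; edges require
strictly |ρ| > 0.7 **and** adjusted p < 0.1 — absolute value, since
negative correlations are as meaningful as positive ones. The
leptin/adiponectin ratio is appended as a derived clinical feature whenever
both parent series are present and adiponectin is positive everywhere.

The network instantiates clinical, metabolite and strain nodes; correlation
edges carry sign/ρ/adjusted p, production edges carry shares (duplicate
records merged with a warning, shares summed; the pipeline averages shares
across samples before building the graph). Strains appear only through
production edges of correlated metabolites; isolated nodes are dropped;
node and edge insertion is sorted so GraphML output is stable.

## Synthetic scenarios

The generator emulates the shape of a 7-timepoint single-subject
intervention: ~10 strains, one producer of a folate-like metabolite whose
abundance rises linearly 5% → 25%, one producer of a branched-chain
ketoacid analogue falling 25% → 5%, one strain planted at 0.05% (below the
cutoff) to exercise filtering, and inert glucose consumers sharing the
remainder with seeded random weights held constant over time. The diet is
fixed across timepoints: glucose 10 mmol/day for growth (biomass demand 0.1
per unit biomass, so the community biomass ceiling of 1.0/day binds, not
the substrate) and each precursor at 200 mmol/day — deliberately in excess,
so the coupling cap `c · a_k · μ + u` is the binding constraint and the
planted secretion series inherit the producers' abundance trends. For chain
templates the expected community net secretion has the closed form

```
min( y · min(S, C), C ),    C = c · a_k · μ_max + u
```

(precursor supply S, molar yield y, filtered renormalised producer
abundance a_k), which the FVA pipeline must match to 1e-6.

Clinical series are built by constructing a rank permutation at the exact
even squared rank distance `Σd² = n(n²−1)(1−ρ*)/6` against a reference
series (enumeration for n ≤ 8, seeded local search above), then assigning
values monotone in rank with jitter small enough to preserve order — so the
planted Spearman ρ is attained exactly, not approximately. Unattainable ρ*
snaps to the nearest lattice value with a warning. Default targets
anti-rank BMI to the folate-like series at |ρ| = 0.8929 and rank leptin /
adiponectin to the two product series, with an untargeted noise parameter
alongside.

What the generator does **not** emulate: genome-scale model size (hundreds
of reactions per strain, promiscuous cross-feeding), compositional noise in
read-derived abundances, missing or tied clinical measurements, and any
host compartment. Passing tests therefore demonstrate the correctness of
the machinery — assembly, coupling, FVA bookkeeping, attribution,
statistics — not the biological fidelity of predictions on real model
collections.

## Numerical and design choices

* LP tolerances 1e-6 absolute on fluxes; FVA range invariant
  `vmin ≤ vmax + 1e-6`. Only the bound values are contractual — vertex
  tie-breaking inside the solver is not.
* All iteration over metabolites/reactions/strains is lexicographic, and
  every writer avoids timestamps, so outputs are byte-stable and rerunning
  a fixed configuration reproduces them bit for bit.
* Tables are tab-separated UTF-8 with `#` metadata lines, 6 significant
  digits by default and full `repr` precision on request.
* The brute-force FVA reference (`gutflux.bruteforce`) parameterises the
  flux polytope on the null space of S and enumerates all vertices from
  square subsystems of active inequalities; it requires finite bounds and
  is exponential in the null-space dimension, which is exactly right for
  the ≤ 8-reaction models it cross-checks.
* Degenerate inputs: a model with no exchanged metabolites yields an empty
  net-flux table with a warning; an infeasible community reports whether
  biomass bounds vs. diet adequacy is the binding conflict; inverted
  bounds fail validation before any solve.

## Problem sizes

The shipped tests and the acceptance script use 10-strain × 7-timepoint
scenarios (~60 reactions per community), 100 random ≤ 8-reaction models
for the oracle cross-check, 20 scenario seeds for the closed-form check,
1000 random permutations / p-vectors for the statistical exactness checks,
and 50 null clinical draws for the edge-retention rate. These sizes were
chosen so the whole suite runs in well under a minute while every property
is exercised at full precision.

## Known limitations

* Single shared lumen pool; no per-strain private environments, mucus or
  oxygen gradients, and no host compartment.
* Steady-state only — no dynamic FBA; communities are assembled per sample
  independently, so temporal coupling enters only through the abundance
  profiles.
* The per-gDW-hour → mmol/day unit conversion between strain interiors and
  the community exchange layer is declared metadata, not an enforced
  physical rescaling.
* The exact permutation p-value is limited to n ≤ 9; beyond that the t
  approximation is the only option.
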