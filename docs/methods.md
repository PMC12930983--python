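# Methods

## Scope

`oxidogem` analyses constraint-based metabolic models of yeasts that catabolize
galactose through two parallel routes: the Leloir pathway (galactokinase →
galactose-1-phosphate uridylyltransferase → UDP-glucose 4-epimerase →
phosphoglucomutase) and an oxidoreductive pathway (aldose/galactose reductase →
galactitol dehydrogenase → L-xylo-3-hexulose reductase → sorbitol dehydrogenase)
whose first step can run on either NADH or NADPH. The package covers model
representation and curation, flux balance analysis (FBA) under nutrient
limitations, random-objective sampling of the flux space, metabolite-turnover
PCA, phenotype classification, reporter-metabolite transcriptome integration and
energetic-parameter fitting. All stages run on any model expressed in the
package's data model (SBML L3+FBC or the native JSON dialect); a built-in toy
model provides a fully controlled test bed.

## Constraint-based model and FBA

A model is the stoichiometric matrix S (metabolites × reactions; negative
coefficients = substrates), flux bounds l ≤ v ≤ u in mmol·gDW⁻¹·h⁻¹, Boolean
gene rules per reaction (`or` = isoenzymes, `and` = complex subunits; empty =
spontaneous), and compartment-tagged metabolite identifiers. FBA solves

    max/min  Z = c'v   s.t.   S·v = 0,   l ≤ v ≤ u

with the dual-simplex/IPM hybrid of HiGHS (via `scipy.optimize.linprog`). The
solver is reached through a minimal contract (matrix, bounds, objective in;
status, v, Z out), so the backend is replaceable. Growth is the flux of a
biomass pseudoreaction producing 1 gDW per flux unit, so its flux is the
specific growth rate in h⁻¹.

Limitation scenarios follow a fixed bound recipe: every exchange may secrete up
to +1000; freely available medium components (O₂, NH₄⁺, Pi, water, protons
unless limiting) take a lower bound of −1000; the limiting exchange (the carbon
source when carbon-limited, otherwise O₂ or NH₄⁺) takes −1 by default while a
non-limiting carbon source is opened to −1000.

### Parsimonious post-processing

FBA optima are usually degenerate. Where a single representative flux vector is
needed (pathway-flux summaries, sampled ensembles), a secondary LP minimizes the
weighted sum of |v| at the fixed optimal Z. Weights encode the parsimony
rationale — minimal enzyme usage: gene-associated reactions weigh 1, while
exchanges and non-enzymatic diffusion pseudo-reactions carry only a 1e-3
tie-break weight. An unweighted penalty would misprice respiration, whose
proton/water bookkeeping moves large fluxes through cost-free transport steps.

## Random-objective sampling

For each scenario, growth is first maximized to obtain v*growth; the growth
reaction is then floored at 0.5·v*growth and a series of FBA problems is solved
(10,000 in the study design; desk-scale runs use 250–2,000), each maximizing a
random objective. A draw selects each reaction with probability
`objective_density` (default 2/n_reactions, i.e. two expected reactions per
objective, following the sparse random objectives of the MATLAB sampling routine
this procedure mirrors; at least one reaction is guaranteed) and assigns i.i.d.
uniform[−1, 1] coefficients. Exchange reactions are eligible. Each accepted
solution is parsimony-post-processed so that secretion statistics reflect fluxes
the random objective actually rewarded or the constraints actually required.
The ensemble explores attainable suboptimal phenotypes; it carries no uniform-
sampling guarantee over the polytope.

All randomness flows through one `numpy` generator seeded per run; samples are
ordered by draw index, so results are bit-reproducible for a fixed
(model, scenario, config) triple.

## Phenotype classification

Per sampled column: a pathway is active when the maximum |v| over its marker
reactions exceeds `flux_epsilon` (default 1e-6 mmol·gDW⁻¹·h⁻¹; a strict-chain
mode requires every marker to carry flux), giving one of
{leloir_only, oxidoreductive_only, dual, none}. A watchlist metabolite
(galactitol, ethanol, D-sorbitol, L-sorbose by default) is secreted when its
exchange flux exceeds `flux_epsilon` (positive = out of the cell). Cofactor
labels compare the NADH-linked against the NADPH-linked galactose-reductase
variants; "prefers NADH" means more total flux through the NADH-linked variant.
Aggregation yields per-condition percentage tables over the carbon-source ×
limitation grid.

## Metabolite turnover and PCA

The turnover of metabolite i in flux vector v is

    tau_i = 1/2 * sum_j |S_ij * v_j|

— the total transformation rate of the metabolite; at steady state it equals
both its production and its consumption. Sampled columns are converted to a
samples × metabolites turnover matrix (extracellular metabolites excluded by
default to avoid double-counting transport) and reduced by mean-centered,
unscaled PCA (`TurnoverPCA`, a fit/transform estimator over scikit-learn's
exact SVD). Loading columns are sign-fixed so the largest-magnitude entry is
positive. The top contributors of a component are all metabolites whose loading
is within one order of magnitude of the extreme loading in the chosen direction
(≥ max/10, or ≤ min/10 for the negative direction) — a scale-invariant rule.
Overlay tables attach per-sample pathway/secretion labels and min-max-normalized
total intracellular ATP turnover to the PC1/PC2 scores.

## Reporter metabolites and co-expression

Gene-level differential-expression p-values map to Z = Φ⁻¹(1 − p) (p clamped
away from 0/1). A metabolite's neighbour genes are those appearing in the rules
of reactions that produce or consume it; compartment duplicates collapse to one
node by default. The metabolite score Z_met = ΣZ_gene/√k is corrected against
the mean and SD of 10,000 random size-k gene sets drawn from the scored
background, converted to a two-sided p-value and Benjamini–Hochberg adjusted.
The conventional significance threshold is adjusted p < 0.001.

Cross-condition co-expression uses Pearson r with the two-sided t-test at
df = n_conditions − 2; zero-variance genes are flagged, never imputed.

## Energetics fitting

Three parameters set the energy economy: GAM (mmol ATP·gDW⁻¹, a biomass
coefficient), NGAM (mmol ATP·gDW⁻¹·h⁻¹, a forced ATP-hydrolysis flux) and the
P/O ratio (ATP per oxygen atom reduced, a stoichiometric coefficient of the
respiratory lump). Chemostats are simulated by fixing growth to the dilution
rate D and minimizing carbon uptake — the frugality convention for a
growth-limited chemostat. Fitting minimizes the RMSE between predicted and
measured carbon uptake, O₂ uptake and CO₂ production, each rate type normalized
by its mean measured magnitude before pooling, over a coarse grid
(GAM 10–120 in 7 steps, NGAM 0–5 in 6, P/O 0.5–3 in 6) followed by Nelder–Mead
refinement clipped to the grid box. The report carries per-rate residuals and
the full grid surface.

**Identifiability.** With only aerobic, carbon-limited observations the three
parameters are *not* jointly identifiable in this model family: every
observable scales with a single "carbon burned for ATP" latent per dilution
rate, so (GAM, NGAM) trade off exactly against the P/O-dependent ATP yield
(RMSE stays ~0 along a one-dimensional ridge). One oxygen-restricted chemostat
observation separates substrate-level from oxidative phosphorylation and makes
the fit well-posed; the parameter-recovery analyses therefore pair the two
aerobic dilution rates (0.05 and 0.1 h⁻¹) with one O₂-capped run
(D = 0.1 h⁻¹, q_O₂ ≤ 1 mmol·gDW⁻¹·h⁻¹). Because the maintenance intercept is
small relative to metabolic rates, recovery under 5% rate noise additionally
uses biological-triplicate replication and a third dilution rate
(0.025 h⁻¹) — the precision any single-shot two-point design cannot deliver.

`update_biomass` rescales the biomass pseudoreaction to measured protein and
lipid mass fractions (the carbohydrate/remainder pool absorbs the balance so
Σ pool-coefficient × pool mass = 1 g·gDW⁻¹), and rebuilds the protein
pseudoreaction from molar amino-acid frequencies scaled by residue masses,
preserving the polymerization ATP cost per residue.

## The synthetic toy model

The toy model condenses the lactose/galactose network of a respiratory,
galactitol-producing yeast into 61 reactions, 51 metabolites, 35 genes and two
compartments: lactose uptake and hydrolysis; the four Leloir steps; the
oxidoreductive chain with a dual-cofactor galactose reductase (NADH- and
NADPH-linked variants sharing gene XYL1_2) plus two NADPH-only isoenzymes;
sorbitol-to-sorbose oxidation; split upper/lower glycolysis with a glycerol
branch; lumped oxidative PPP (12 NADPH per glucose-6-phosphate fully oxidized);
lumped TCA; oxidative phosphorylation parameterized by P/O; an ethanol branch;
a pyruvate overflow exit; amino-acid, lipid and carbohydrate synthesis feeding
a biomass pseudoreaction with GAM, and a fixed-flux NGAM reaction. All internal
reactions whose metabolites carry formulas balance C, H, O, N and P exactly.

Defaults bake in the study conditions: GAM = 60 mmol ATP·gDW⁻¹, NGAM = 1.0
mmol ATP·gDW⁻¹·h⁻¹, P/O = 1.5, biomass 45% protein / 7% lipid / 48%
carbohydrate-remainder — conventional budding-yeast values. Three structural
choices matter for overflow behaviour and were validated against the published
physiology pattern rather than fitted:

- **Fixed NGAM (lb = ub).** Cells cannot dissipate arbitrary ATP; with a free
  ATP-waste valve, sampled ensembles dispose of excess carbon fermentatively
  under every limitation and the condition structure of overflow collapses.
- **Glycerol branch and pyruvate exit.** Real yeast networks offer short
  redox/carbon relief valves besides ethanol. Without them, any
  carbon-pulling objective is stoichiometrically forced into ethanol; with
  them, ethanol secretion concentrates where it is genuinely required —
  oxygen-limited ATP supply — while nitrogen-limited excess carbon leaves as
  galactitol (coupled to NADH reoxidation) or glycerol.
- **Redox-coupled galactitol.** The NADH-linked reductase makes galactitol an
  NADH sink, so oxygen or nitrogen limitation elicits galactitol overflow the
  way ethanol overflow appears in fermenting yeasts, and galactitol can be
  re-assimilated through the oxidoreductive chain (the Leloir-cluster deletion
  strain grows on galactitol as sole carbon source).

What the toy does *not* emulate: compartmentalized redox shuttles and proton
economics, the real model's thousands of promiscuous/parallel routes (which
dilute rare sampling events — toy secretion percentages under carbon/nitrogen
limitation are several percent where a genome-scale network reports ~0–1%),
enzyme capacity, and regulation. Passing toy tests therefore demonstrates
correctness of the machinery and qualitative condition structure, not
quantitative agreement with any genome-scale model.

## Numerical choices

- LP feasibility/optimality at HiGHS defaults; steady state asserted to 1e-6.
- "Carries flux" threshold 1e-6 mmol·gDW⁻¹·h⁻¹ everywhere, configurable.
- Default bounds when a file omits them: (−1000, 1000) reversible, (0, 1000)
  irreversible; magnitudes clipped to ±1000.
- p-values of 0 clamped to the smallest positive float before Φ⁻¹.
- PCA uses exact full SVD; degenerate (constant) turnover matrices are
  rejected rather than silently producing noise components.
- Infeasible draws during sampling are redrawn up to 50 times and counted;
  an infeasible scenario reference aborts with a scenario error.
- Grid/refinement fitting treats infeasible parameter points as missing, not
  as large penalties, except inside the Nelder–Mead objective (1e6).

## Problem sizes

Desk-scale analyses use 40–2,000 samples per scenario (the acceptance script
uses 2,000 across the six-condition grid; stochastic percentages are stable to
roughly ±2 points at that n), background correction with 3,000–10,000 draws,
and the fitting grids above. All analyses are deterministic given the seed.

## Known limitations

- Randomized-objective FBA characterizes reachable corners of the flux
  polytope, not a probability distribution over it; percentages depend on the
  objective law (documented above) and on network granularity.
- The exact marker-reaction sets defining "pathway usage" are configuration;
  defaults are shipped for the toy model only.
- Elemental validation skips reactions involving formula-less pseudo-species
  (biomass pools), and exchange pseudo-reactions by construction.
- SBML round-tripping preserves structure and semantics but normalizes
  identifiers (compartment-suffix form) and redundant rule parentheses.
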