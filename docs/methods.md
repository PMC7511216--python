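# Methods

## Scope and data flow

The package models the central carbon metabolism of *Bacillus methanolicus*
MGA3 under three growth conditions — methanol, mannitol and d-arabitol —
and estimates intracellular fluxes from ¹³C labeling data. Because the
original instrument data are not bundled, a synthetic-data module generates
every input at the study conditions with known ground truth; the analysis
chain itself (correction → simulation → fitting → interpretation) is
agnostic to whether its inputs are synthetic or real.

## Network models

Atom-transition models are plain-text files (one reaction per line with
bracketed atom letters). The three bundled models share nomenclature and
general topology:

- **methanol**: RuMP cycle (hps/phi) with explicit glycolytic and PPP
  intermediates, cyclic dissimilation via zwf/gnd, a lumped linear
  formaldehyde detoxification branch (`detox`, carrying the
  methylene-THF-dehydrogenase NADPH, formate-dehydrogenase NADH and
  formate-THF-ligase ATP stoichiometries in the cofactor map), both SBPase
  (`sba`/`glpx`, glpX irreversible) and transaldolase (`ta`) regeneration
  variants, full TCA with explicit aconitate, and an explicit CO₂ pool so
  that labeled CO₂ can be re-assimilated by pyruvate carboxylase.
- **mannitol**: PTS uptake lumped into `manupt` (mannitol → Fru6P, NADH),
  acetate overflow exported from acetyl-CoA (`out_Ac`), and glycolytic
  intermediates lumped (no separate DHAP/PGA pools; aldolase cleaves FruBP
  into two trioses directly), as a stationary analysis does not require
  them.
- **arabitol**: both candidate PTS entries. The C1 route phosphorylates at
  C1; oxidation of arabitol 1-phosphate creates the carbonyl at what
  becomes C2 of Xyl5P, and ketose renumbering from the new carbonyl end
  **reverses** the carbon order (arabitol C1 ↔ Xyl5P C5). The C5 route
  retains the order (arabitol Ci ↔ Ribu5P Ci). Under [5-¹³C]arabitol the
  two routes therefore label opposite ends of the pentose-phosphate pool —
  the signature the route discrimination exploits (verified as a test:
  Rib5P C1 enrichment > 0.5 under the C1 route, C5 > 0.5 under the C5
  route).

Phosphoenolpyruvate carboxykinase is excluded from all three models, and
the glyoxylate shunt is not modeled. Succinate and fumarate are flagged
rotationally symmetric (the standard TCA convention); free d-mannitol is
also symmetric (C2 axis), so [1-¹³C]mannitol scrambles 50/50 into Fru6P
C1/C6. d-Arabitol is treated as asymmetric: the PTS distinguishes the two
ends chemically, which is the entire premise of the route question.

Biomass formation is modeled as per-precursor drain reactions (`bm_*`)
whose fluxes are demand coefficient × growth rate. The demand coefficients
bundled with the models are generic textbook precursor requirements
(mmol/gDCW) — placeholders, since organism-specific values for
*B. methanolicus* are not established; they are data, editable in the
model files.

## Labeling simulation

The simulator tracks **tracer atoms only**: natural isotope abundance is
removed from raw MS data by the correction module, so an unlabeled input
yields M+0 = 1 everywhere. Tracer purity (default 0.99) is applied when
the label input is expanded: each nominally labeled position carries ¹³C
with probability equal to the purity.

The EMU decomposition walks backwards from the requested observables
(full-molecule CIDs, single-carbon enrichments, and the subset fragments
needed for ¹³C-¹³C multiplet fractions). Reversible reactions contribute
forward and backward terms via the net + exchange decomposition
(fwd = max(v,0)+exch, bwd = max(−v,0)+exch). Symmetric metabolites are
orientation-averaged with weight ½ at the point where their pool is
filled. Stationary blocks are dense linear solves per fragment size;
fragments with zero inflow at the given fluxes (dead branches) are set to
M+0 = 1 by convention. Multiplet fractions around an anchor carbon are
reconstructed from subset-fragment CIDs by inclusion–exclusion over the
"all positions labeled" moments — an identity, not an approximation —
and are tested against direct summation over the exhaustive isotopomer
distribution.

The instationary solver integrates the same cascade with
d(x_e)/dt = (inflow(t) − outflow·x_e)/pool, using a BDF integrator with
the exact (constant, linear) per-block Jacobian, relative tolerance 1e-8
and absolute 1e-10 by default (1e-6/1e-8 inside iterative fitting). Pools
are µmol/gDCW, fluxes mmol/gDCW/h, times hours; the rate constant of a
pool is flux × 1000 / pool per hour. The closed form M+0(t) = exp(−vt/P)
of a single pool is a regression test.

The exhaustive isotopomer oracle relaxes the full positional balance over
all 2ⁿ states per metabolite (Gauss–Seidel, tolerance 1e-12). The
stationary balance is bilinear in the isotopomer fractions for condensation
reactions, so a single linear solve does not exist; fixed-point relaxation
converges on all bundled cases and the oracle is capped (default 2¹⁸
states) to keep it an oracle, not a production path. EMU CID marginals
agree with the oracle to better than 1e-8 on six structured toys
(condensation, cleavage, reversible exchange, symmetry, order-scrambling
branches, RuMP-like C1 condensation).

## Natural-abundance correction

The correction matrix maps tracer-isotopologue fractions to observed
mass-shift fractions: column j is the binomial of tracer purity over the j
labeled positions, convolved with natural ¹³C on the remaining carbons
and, in low-resolution mode, with the natural mass-shift distributions of
every other element (H, N, O, S, Si, P; bundled IUPAC abundances,
overridable). High-resolution mode — only ¹³C interferes — is the
default, matching Orbitrap-class acquisition. Inversion is non-negative
least squares followed by renormalization, so noisy spectra cannot produce
negative fractions; the residual norm is reported.

## Flux estimation

Free net fluxes are a deterministic basis of the nullspace of the internal
stoichiometric matrix augmented with equality constraints (measured fluxes,
biomass drains): Gaussian elimination pivots columns in lexicographic
reaction-id order, so the same model and constraints always select the
same free fluxes. Exchange fluxes of reversible reactions are free
parameters on [0,1) via x/(1−x) when fitted.

The objective is the variance-weighted SSR over CIDs, positional
enrichments, coupling fractions, measured rates and (in instationary mode)
CID time courses; parallel labeling datasets contribute concatenated
residual blocks. Optimization is bounded trust-region least squares with
Latin-hypercube multi-start (default 10 starts, seeded); start candidates
violating irreversibility constraints are used only as a fallback, because
labeling residuals carry no gradient outside the feasible flux cone (a
smooth hinge penalty still pulls strays back). Goodness of fit is
SSR ≤ χ²₁₋α(dof) with dof = measurements − free parameters and α = 0.05;
Monte Carlo precision (default n = 100) resamples measurements around the
best simulation, refits from the best point, and reports per-flux sd and
central 95% intervals, with a warning when more than 20% of refits fail.
Flux minimization for poorly resolved reactions minimizes |v| per reaction
subject to the fit staying χ²-acceptable (SLSQP with a smoothed absolute
value), giving lower bounds in the spirit of reporting unresolved
anaplerotic fluxes conservatively.

Label-design scoring is a local, linearized evaluation: simulate the
candidate measurement set at a reference flux state, form the weighted
Jacobian with respect to the free net fluxes, and propagate the
pseudo-inverse covariance onto the fluxes of interest; directions not
constrained by the data are reported as infinite sd and flagged. The
[5-¹³C]arabitol optimality for route discrimination holds at the
exclusive-Xyl5P-entry reference state — the hypothesis the design
addressed; at an even-split reference other single tracers can score
better, which is consistent with a 1-¹³C/2-¹³C mixture also being used to
probe simultaneous operation of both routes.

## Post-fit analyses

- **Normalization**: flux × total reactant carbons ÷ substrate carbon
  uptake (C-mmol/C-mmol); the substrate uptake maps to 1 and, for a
  carbon-balanced map, total normalized outflow (CO₂ + products + biomass
  drains) is exactly 1.
- **Cofactor balance**: reaction-to-cofactor stoichiometries ship as an
  editable JSON data file (producers/consumers for NADPH, NADH, FADH₂,
  ATP; PTS uptakes consume one ATP equivalent). The full NADH/FADH₂
  surplus is routed to oxidative phosphorylation at P/O 1.5 and 1.0; an
  "unknown" term closes every balance exactly and is asserted as an
  identity. Biomass cofactor requirements default to placeholder values
  (mmol/gDCW × growth rate) and should be overridden when
  organism-specific measurements exist.
- **Route discrimination**: three fits (C1-only, C5-only, both free) with
  the excluded entry constrained to zero; χ² verdict per variant; the
  both-free variant reports the fitted route split. Failures in one
  variant do not abort the others.
- **Subnetwork flux from label dynamics**: a two-reaction model
  (precursor → target, target → sink at equal rate) fitted to the target
  M+0 profile, d(M0_t)/dt = (v/pool)(M0_p − M0_t), with exact exponential
  propagation between sample points (precursor linearly interpolated).
  The precursor profile can be rescaled so its plateau matches the
  target's isotopic steady state, absorbing an unlabeled extracellular
  contribution. Monte Carlo (default n = 200) gives the flux sd. Only
  v/pool shapes the curve; v is identified because the pool is measured.
- **Physiology**: growth rate from log-linear OD regression; uptake and
  production rates from the slope of concentration against biomass
  (ds/dX = −q/µ during balanced exponential growth); OD→gDCW conversion
  factors 0.389 (bioreactor) and 0.22 (flask) g/L per OD₆₀₀ unit.
- **Reconciliation**: classical weighted least-squares projection of
  measured rates onto elemental conservation constraints,
  r* = r − S Eᵀ(E S Eᵀ)⁻¹E r, with a χ² consistency statistic on the
  constraint residuals. Biomass carbon content follows from
  CH₁.₆₄₆N₀.₂₁₉O₀.₄₁₀S₀.₀₀₅ with 6% ash (≈ 40 mmol C/gDCW).

## Synthetic data

The generators emulate the study conditions: growth rates 0.46 / 0.36 /
0.14–0.15 h⁻¹ and carbon uptakes 30.6 / 36 / 24.5 C-mmol/gDCW/h for
methanol / mannitol / arabitol; label inputs [¹³C]methanol,
[1-¹³C]mannitol, [5-¹³C]arabitol (and the 9:1 [1-¹³C]/[2-¹³C] mixture as a
design candidate); acetate overflow 1.75 mmol/gDCW/h on mannitol only; 13
sampling points over 3.5 min for the methanol pulse. Remaining degrees of
freedom of each reference flux state are set once to round values
consistent with the published flux maps. Amino-acid labeling is
represented by the CIDs of the corresponding precursor pools (pyruvate for
alanine, oxaloacetate for aspartate, ...); the hydrolysis layer adds no
information in a synthetic setting and the amino-acid↔precursor carbon
mappings are not part of the bundled models.

Noise models: truncated Gaussian (absolute sd, default 0.005) on CID
entries followed by renormalization to the simplex; Gaussian sd 0.01 on
enrichments and coupling fractions; 5% CV on rates; multiplicative
Gaussian on assay rates with negative draws clipped at zero and flagged.
Every generator takes a seed and regenerates bit-identically.

Methanol-model pool sizes are order-of-magnitude defaults chosen once so
that the labeling transient spans the few-minute sampling window (larger
pools on upper glycolysis, smaller on low-concentration intermediates);
they are not measured values.

**What passing tests do and do not show.** Synthetic data share the
model's topology and noise assumptions by construction, so recovery tests
demonstrate the correctness and identifiability of the estimation
machinery — not that the bundled networks are a complete description of
*B. methanolicus* metabolism, nor that real MS noise is Gaussian and
independent. Model misspecification, correlated instrument noise and
amino-acid-specific fragmentation effects are outside what these tests can
certify.

## Numerical choices and problem sizes

- Stationary EMU solves: dense `numpy.linalg.solve` per size block; the
  bundled models produce a few hundred fragments.
- Parameter recovery demonstrations run with exchange fluxes held at their
  reference values; most exchanges are structurally unidentifiable from
  the synthetic measurement sets, and co-estimating them is supported but
  not part of the recovery criteria. Instationary fitting likewise keeps
  pool sizes fixed at their known values rather than co-estimating them.
- The methanol recovery uses the 13-point 3.5-min grid with 7 measured
  species; the route discrimination uses ~70 measurements per dataset;
  Monte Carlo interval coverage uses 50 replicates × 100 resamples on a
  two-branch toy network. These sizes make the full suite and the
  acceptance script each run in a few minutes on one CPU.
- Reported ratios follow the printed precision of the source tables (one
  decimal below 10, integer above); full precision is retained internally.

## Known limitations

- FTBL/SBML import is not supported (SBML export of stoichiometry only
  could be added; atom maps would travel in annotations).
- One compartment; no thermodynamic or cofactor constraints inside the
  fit itself (cofactor balancing is a post-hoc analysis, as in the study
  design).
- The exhaustive oracle is exponential in carbon count and intended for
  verification only.
- Biomass precursor demands and cofactor requirements are placeholder
  values pending organism-specific measurements.
- The subnetwork dynamic fit assumes a single well-mixed target pool and a
  measured pool size; pool mis-estimation propagates linearly into the
  flux.
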