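# Methods

## Model and assumptions

The core object is a genome-scale stoichiometric model: metabolites × reactions
matrix **S**, per-reaction flux bounds, gene-protein-reaction (GPR) boolean
rules, and a lumped biomass reaction whose flux is the specific growth rate μ
(1/h). Flux balance analysis (FBA) solves

    max  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub

with c the objective weights (biomass weight 1 by default). The steady-state
assumption S·v = 0 means no internal metabolite accumulates; exchange
pseudo-reactions (`met ↔ ∅`, coefficient −1) carry the boundary fluxes, with
uptake as negative flux, so an uptake capacity of u mmol/gDW/h is the lower
bound −u on the exchange.

### Degenerate optima and parsimonious resolution

The LP optimum μ* is unique, but the optimal flux vector generally is not.
Because downstream analyses correlate per-reaction flux *profiles* with
expression, a reproducible vector is required. Every solve used for
correlation is therefore post-processed with a parsimonious secondary LP:
minimize Σ|v| subject to the original constraints plus c·v ≥ μ*(1 − ε),
ε = `optimum_tol` (default 1e−9). This selects a unique minimum-total-flux
vector and zeroes closed internal cycles, at the cost of a bounded backoff in
flux of order ε·μ* (visible at the 1e−8 level; all flux comparisons in tests
use 1e−6, the mass-balance scale). The flux time series records whether plain
or parsimonious resolution was used.

### Time-resolved FBA of the fermentation

The fermentation is modeled as a sequence of *independent* steady states, not
an ODE-coupled dynamic FBA: at each sampled time point the measured nutrient
uptake rates become exchange bounds (the input function) and the LP is
re-solved. No biomass integration or byproduct feedback is performed — only
the constraints and the objective vary with time. The default time grid
mirrors the sampling design of the emulated fermentation: hourly from 20 to
44 h, two-hourly from 46 to 60 h. Measured rates are filled onto the grid by
piecewise-linear interpolation and never extrapolated beyond the measured
window; a measured rate of exactly zero (a depleted nutrient) becomes a hard
zero uptake bound.

### The dynamic objective (metabolic switch)

Before the switch time (default 34 h, phosphate depletion) the objective is
pure biomass. From the switch on, antibiotic production enters the objective.
Two encodings are provided because "shifting biomass composition toward
antibiotics" is genuinely ambiguous:

* **weighted** (default): each antibiotic exchange gains weight
  β_k(t) = `weight_scale` · r_k(t)/(MW_k·1000), where r_k(t) is the measured
  production rate in μg/gDW/h and MW_k the molecular weight in g/mol (taken
  from the model species' formula when not given; the bundled antibiotic
  formula C32H26O14 gives 634.5 g/mol). The proportionality constant
  `weight_scale` is dimensionless and exposed because no canonical value
  exists.
* **forced**: the objective stays pure biomass and each antibiotic exchange
  flux is pinned to its molar-converted measured rate. This encoding is used
  for the synthetic study because it makes the antibiotic flux profile — and
  hence the ground truth for genes on that pathway — deterministic and
  non-zero after the switch regardless of the weight scale.

With zero antibiotic rates both encodings reduce to pure biomass, so the
objective (and μ) is continuous at the switch.

### Chemostat validation

At steady state in a chemostat the specific growth rate equals the imposed
dilution rate D, so observed D can be compared directly with the FBA-predicted
μ under the measured exchange rates. Glucose and O2 are applied as uptake
caps (lower bound −rate, upper 0); CO2 and actinorhodin are *measured
productions*, applied by default as equalities (lower = upper = rate), with a
`cap` mode available since the original protocol is ambiguous on this point.
Actinorhodin rates printed in μg/gDW/h are converted to mmol/gDW/h via the
molecular weight.

## Transcriptome–flux integration

* **Matching**: each gene maps to exactly one reaction — among the reactions
  its GPR mentions, the one with the largest time-mean |flux| over the whole
  course ("maximum predicted flux"), ties broken by lexicographic reaction id
  so the matching is deterministic. A per-timepoint-maximum variant is
  available behind a flag; the whole-course mean is the default because it is
  stable under single-timepoint noise.
* **Correlation**: Pearson r between the matched reaction's flux profile and
  the gene's raw log2 expression profile (no z-scoring; r is invariant under
  positive affine transforms anyway). Genes whose matched flux is identically
  zero (`zero_flux`), constant (`constant_flux`, zero standard deviation —
  typically maintenance), or whose expression is constant are excluded with
  the reason recorded rather than assigned r = 0.
* **Classification**: correlated if r > 0.5, anticorrelated if r < −0.5,
  else uncorrelated (thresholds configurable). No significance testing or
  multiple-testing correction is applied: the classes are descriptive.
* **Screens**: zero-flux genes (matched flux zero at every time point) flag
  candidate model gaps when their expression is nonetheless dynamic;
  "essential" genes (non-zero matched flux at *every* time point) are
  expected to be expressed, and essential genes whose median log2 expression
  falls below 5.0 (configurable) are flagged as candidates for redundant
  annotation or probe failure. Expression times are aligned to flux times by
  nearest neighbor within 1 h; unmatched points are dropped with a warning.

## Clustering

Expression profiles are clustered by temporal shape: per-gene z-scoring, then
agglomerative clustering with average linkage on correlation distance
(1 − Pearson r between profiles), tree cut to k = 12 clusters by default.
Both the metric and the standardization are configurable: shape-based
defaults are a modeling choice, and recovering groups that differ only in
absolute *level* requires euclidean distance without standardization. Flat
(zero-variance) profiles get correlation distance 0 to each other and 1 to
every varying profile, which keeps the distance matrix finite and the
procedure deterministic. Cluster labels are arbitrary and are relabeled by
decreasing size (ties by smallest member id). Cutting the same tree at k and
k+1 yields nested partitions. The genome-order track joins cluster id and
correlation class per gene in chromosomal order (lexicographic gene id by
default, an explicit order list otherwise).

## Synthetic data: what it emulates and what it does not

The generator produces branch/chain toy networks feeding a pooled biomass
precursor, so the optimal growth rate has the closed form
μ* = (Σ_b u_b − m)/d (u_b branch uptake capacities, m pinned maintenance
flux, d biomass demand). Defaults model the emulated study's conditions:
three active nutrient branches (phosphate, glucose, glutamate) at
10 mmol/gDW/h capacity, phosphate ramping to zero at the 34 h switch and
glutamate at 56 h, one permanently blocked branch (the zero-flux gene set),
maintenance flux 0.2 mmol/gDW/h (the constant-flux gene set), an antibiotic
pathway whose production rises at 50 μg/gDW/h per hour after the switch, 200
genes, and additive Gaussian noise of 0.1 log2 units on unit-variance flux
shapes. Genes are assigned blockwise to reactions (synthetic operons, with
isozyme `or` groups, some `and` complexes and some multi-reaction genes).
Among varying-flux genes, 55% are labeled correlated (positive affine
transform of the matched flux shape), 15% anticorrelated (sign-flipped,
emulating misannotation), 5% unexpressed (flat at the 4.5 control floor) and
the rest uncorrelated (flat at a gene-specific baseline); the constant-flux
and zero-flux labels arise structurally from the maintenance reaction and the
blocked branch rather than from dials. Ten negative-control probes sit at
the floor.

What passing the recovery tests shows: the pipeline's matching, correlation,
classification, screening and clustering machinery is correct and
deterministic under the stated noise. What it does not show: anything about
microarray normalization artifacts, probe-level noise structure,
post-transcriptional regulation, or the fidelity of any particular
genome-scale reconstruction — real expression–flux correlation is far weaker
and more heterogeneous than the affine generator produces.

The 2-group clustering recovery is evaluated on the correlated and
sign-flipped genes matched to a single flux shape (the depleting phosphate
branch), where the two groups are exact mirror images; across branches the
sign groups span several shapes and no 2-cluster solution could (or should)
separate them.

## Numerical choices

* LP backend: HiGHS via `scipy.optimize.linprog`; primal feasibility
  tolerance 1e−9 (configurable).
* Mass-balance check: max |S·v| ≤ 1e−6 for every optimal vector.
* Zero-flux tolerance: |v| ≤ 1e−9.
* Parsimonious optimum tolerance: 1e−9 relative (see above).
* Unbounded LPs report a best-effort culprit reaction (an objective-weighted
  reaction with an infinite bound in the improving direction); infeasible
  time points in a dynamic run yield NaN columns and a recorded status, never
  silent omission.
* Problem sizes: the synthetic study uses 33 time points × ~25 reactions ×
  200 genes; the LP-vs-enumeration equivalence check uses 100 random networks
  of 6–10 reactions (the brute-force vertex oracle is exponential, so sizes
  are kept where full enumeration stays exact and quick).

## Known limitations

* The genome-scale *S. coelicolor* model and the fermenter rate series of the
  emulated study are external artifacts; the structural-count and published
  chemostat-panel checks require that SBML file and report its absence
  explicitly. Everything else is validated on synthetic ground truth.
* Kind inference (exchange/transport/biomass/maintenance) is heuristic for
  models that do not annotate kinds; the summary reports whatever partition
  the input supports.
* No flux variability analysis, knockout simulation, regulatory constraints,
  or expression-constrained FBA — out of scope by design.
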