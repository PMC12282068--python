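# Methods

## Enzyme-constrained model formulation

A stoichiometric model (metabolites × reactions matrix **S**, flux bounds
lb ≤ v ≤ ub, fluxes in mmol/gDW/h) is converted to an enzyme-constrained model
in the GECKO style:

* every reaction with a turnover number is made irreversible; reversible
  reactions are split into `__fwd`/`__rev` arms, each coupled independently
  (for reporting, the net flux is fwd − rev);
* each enzyme *i* becomes a pseudo-metabolite produced by an enzyme-usage
  pseudo-reaction with flux v_enzyme,i (mmol enzyme/gDW/h through the usage
  reaction, numerically equal to the enzyme amount sustaining the coupled
  fluxes) and consumed by each catalyzed reaction *j* with coefficient
  1/kcat_ij (kcat in 1/h), enforcing v_j ≤ kcat_ij · e_i;
* usage reaction *i* draws mw_i grams (mw in g/mmol) of a shared protein-pool
  pseudo-metabolite, supplied by a pool-exchange reaction bounded above by
  the pool capacity (g catalytic protein/gDW).  The pool-exchange flux
  therefore equals Σᵢ mw_i · v_enzyme,i at every feasible point.

The pool capacity is condition-dependent and has no universal default; it is
a required user input of `build_ec_model`.  Isozymes default to parallel
arms (one reaction copy per isozyme); a "fastest kcat only" policy is
selectable.  Enzyme complexes are modeled as one pseudo-enzyme with a summed
molecular weight — subunit stoichiometry is not represented.

## Static objectives

All objectives are linear programs solved with HiGHS (`scipy.optimize.linprog`,
presolve on; solver feasibility/optimality tolerances 1e-9).

* **FBA** maximizes one reaction flux (growth, a product exchange, the
  maintenance reaction, or a custom linear form).  Because alternate optima
  are common and the dynamic simulations need a deterministic reference, a
  lexicographic second stage fixes the achieved optimum and minimizes total
  enzyme usage (on by default).
* **MORP** minimizes Σᵢ |v_enzyme,i − v_enzyme,i,ref| subject to the model's
  constraints.  The L1 objective is linearized exactly, not heuristically; the
  default formulation introduces one auxiliary dᵢ per enzyme with
  dᵢ ≥ ±(v_enzyme,i − refᵢ), and an independent split-variable formulation
  (uᵢ − refᵢ = pᵢ − qᵢ, p,q ≥ 0) is kept for cross-checking — the test suite
  asserts both return equal optima, and that the optimum matches dense
  enumeration of small polytopes.  Deviations are summed in the native
  mmol/gDW/h usage units; a mass-weighted (g-of-protein) variant is available
  via `mass_weighted=True`.  MORP imposes no growth or maintenance floor
  beyond the model's own bounds.
* **Minimal total proteome** fixes measured exchange rates (bounds may only
  touch exchange reactions) and minimizes the pool-exchange flux: the most
  efficient enzyme usage consistent with the observed physiology.

## Dynamic simulation (static optimization approach)

Batch culture is integrated on a fixed grid with explicit Euler steps
(default dt = 0.1 h).  For interval *k*, each active substrate's uptake bound
is the Monod rate at the previous interval's concentration,
v_s,k = v_s,max · [S]ₖ₋₁ / (Km + [S]ₖ₋₁), imposed as an equality by default
(the `upper` sense is available because an equality can be infeasible when
the protein pool or maintenance floor binds; both senses are supported).
After solving the interval LP, biomass advances as X ← X(1 + μ·dt) and each
tracked extracellular species as C ← C + v_exchange · mw · X · dt.  Trace
negative concentrations (> −1e-6 g/L) are clamped to zero; larger undershoots
raise a step-size error.  An optional first-order biomass decay rate exists
(default 0); the lag-phase biomass decline seen in real cultures is not
reproduced mechanistically.

Schedules are ordered phases, each with an objective and an exit condition
(species depletion below a threshold — default 0.01 g/L — or a time).  A
final phase's condition ends the run early; otherwise the run completes at
t_end (with a warning if a switch never fired).  Within a dMORP phase the
reference is rolled forward: interval *r* minimizes
Σᵢ |v_enzyme,i,r − v_enzyme,i,r−1|, and the first dMORP interval uses the last
solution of the preceding phase.  Phases may restrict which substrates carry
Monod bounds (`active_substrates`); inactive substrates are closed.  This
models hierarchical, catabolite-repressed uptake — an equality Monod bound on
*every* substrate would force co-utilization in the first phase, which is the
wrong physiology for a diauxic culture; the co-utilization scenario variant
simply activates both sugars.  Measured concentration series can constrain
exchanges per interval: apparent specific rates (ΔC / (mw · X · Δt)) are
linearly interpolated in time and widened into a relative+absolute band.

## Flux-space sampling

`sample_flux_space` runs a hit-and-run walk on
{v : S·v = 0, lb ≤ v ≤ ub}.  Fixed coordinates (lb = ub) are pinned into the
equality system.  Warm-up points are the FVA vertex solutions; the chord
directions are random Gaussian combinations of (vertex − center) differences
rather than raw null-space vectors, because coordinates that are structurally
blocked (zero in every feasible point while their box bounds are loose —
e.g. an irreversible branch whose cofactor balance forbids flux) would
otherwise collapse almost every chord to a point.  Burn-in defaults to
100 × the polytope dimension and thinning to 100 walk steps per recorded
sample; iterates are re-projected onto the equality manifold every 256 steps
and at each recorded sample, so samples satisfy S·v = 0 to ~1e-12 and the
bounds exactly.  The walk is fully determined by the seed.  A
zero-dimensional polytope yields copies of the single feasible point with a
warning.  The sampler makes no exact-uniformity claim; it is used for
qualitative range comparisons (is an objective-based prediction inside the
unbiased feasible range?).

## The synthetic lactic-acid-bacterium fixture

`make_toy_ccm` generates a 19-reaction central-carbon network (28 after
enzyme augmentation, 9 lumped enzymes) with the two competing fermentation
routes: glucose/trehalose uptake (trehalose → 2 hexose-phosphates), lumped
upper EMP (PFKA) and lower glycolysis (GAPD), LDH, a lumped
oxidative/phosphoketolase shunt (XFP: hexose-P → GAP + acetyl-P + CO₂ +
2 NADH), acetate kinase, an acetyl-P → ethanol branch, an acetoin branch, a
lumped biomass drain (5 mmol hexose-P + 75 mmol ATP per gDW) and an NGAM ATP
floor (0.3 mmol/gDW/h).  ATP and NADH are carried as carbon-free pseudo-
moieties (formulas "P" and "H2") so the carbon balance of every reaction is
checkable; hydrogen/oxygen/phosphorus are not balanced in the lumped
reactions.  Per hexose unit, the EMP route yields 2 lactate and 2 net ATP
(the 1 g/g homolactic yield); the phosphoketolase route yields 1 lactate +
1 ethanol + 1 CO₂ and 1 net ATP, and its redox closure forces the
acetate/acetoin branches to zero in this reduced network — heterolactic
byproduct formation appears as ethanol.

Calibration, which the generator enforces and reports as an explicit error
when violated: the phosphoketolase-branch enzymes are catalytically much
cheaper than the slow lumped upper-EMP step (usage per hexose unit
3.9e-5 vs 2.2e-4 mmol/gDW at the default kcats; the guard requires ≤ 0.5×).
Growth maximization on fast glucose uptake still prefers EMP for its higher
ATP yield, while after glucose depletion — where the rolling reference is the
small near-depletion usage vector — the reallocation-minimal solution routes
the forced trehalose influx through the cheap phosphoketolase branch.  The
glucose Km (2 g/L) is set so uptake tapers over several intervals instead of
crashing through the switch threshold in one 0.1-h step: with a sharp crash
the last glucose-phase reference still carries a large EMP usage, and staying
homolactic would then *be* the reallocation-minimal behavior.  The packaged
scenario uses 20 + 20 g/L sugars, 0.4 gDW/L inoculum, a 0.05 g/L glucose
switch threshold (the maintenance floor needs ~0.15 mmol/gDW/h glucose
uptake, so switching earlier keeps the equality-uptake LP feasible), and
t_end = 18 h, chosen so the trehalose phase ends well above the concentration
at which Monod-limited ATP could no longer cover maintenance.

Monod parameters (glucose: v_max 12 mmol/gDW/h, Km 2 g/L; trehalose: v_max
1.5 mmol/gDW/h, Km 1 g/L), kcats (5e3–2e5 1/h) and molecular weights
(35–110 kDa) are round, physiologically plausible magnitudes for a
small-genome fermenter, fixed once as the package's study conditions.  The
measurement generator subsamples a trajectory (default hourly), adds
zero-truncated Gaussian noise (default σ = 0.5 g/L), and is seeded.

What the fixture does *not* emulate: genome-scale redundancy (hundreds of
enzymes, isozymes, moonlighting), amino-acid uptake and anabolism, pH and
neutralization chemistry, lag-phase death, or measured kinetic parameters of
any real strain.  Passing tests on it demonstrate the algorithms' contracts
and the qualitative transition mechanism, not quantitative agreement with any
organism.

## Analysis conventions

Yields are (ΔC_product)/(−ΔC_substrate) in g/g over a time window, with
consumption required positive.  Relative fluxes are |v_j| as a percentage of
glucose-equivalent uptake, counting disaccharide uptake twice.  Enzyme-usage
fold changes are log2((u + ε)/(u_ref + ε)) with ε = 1e-9 mmol/gDW/h so 0/0
reads 0.  RMSE between predicted and measured product concentrations
interpolates the prediction linearly onto the measurement grid and pools
squared errors over all products and times by default (a per-product-averaged
mode exists; pooling is the default because it weights densely sampled
products proportionally).

## Numerical choices and known limitations

* LP statuses are returned, not raised (`optimal`/`infeasible`/`unbounded`);
  dynamic steps convert infeasibility into an error carrying the interval
  time and active bounds.
* Steady-state residuals of returned solutions satisfy
  ‖S·v‖∞ ≤ 1e-9·max|v| + 1e-9 (asserted in tests).
* Explicit Euler is first-order: halving dt from the default changes
  phase-end concentrations of the packaged scenario by < 2% (or < 0.05 g/L
  for near-zero endpoints, where a relative criterion is meaningless); the
  residual sensitivity is dominated by the biomass discretization error,
  which is why the fixture's growth rate (~0.24 1/h) and inoculum were chosen
  as they are.
* SBML round trips preserve stoichiometry, bounds, and objective; reaction
  *kinds* are re-inferred by convention (single-metabolite reactions →
  exchange, the objective → biomass, ATPM/NGAM ids → maintenance).  The JSON
  dialect is lossless for enzyme-constrained models (enzymes, kcats, pool).
* `fva` raises on infeasible models rather than returning per-reaction
  statuses.
* Sampler uniformity is approximate (coordinate-free hit-and-run mixes
  slowly on elongated polytopes); only range statements are made from it.
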