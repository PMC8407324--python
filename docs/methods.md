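# Methods

This note records the scientific and numerical choices behind
`phasedfba`: what the model assumes, what the toy system emulates and
does not, and where the design was genuinely open.

## Model structure and assumptions

The framework couples a phase-specific parsimonious FBA problem to an
ODE model of the extracellular medium (the "static optimization"
formulation of dynamic FBA: one LP per right-hand-side evaluation).
Core assumptions:

- **Pseudo steady state.** Intracellular metabolism equilibrates much
  faster than the medium changes, so `S·v = 0` holds at every instant
  and all dynamics live in the extracellular states and the biomass
  pools.
- **Phase-dependent objectives.** Cells maximize ATP production during
  lag, growth during the exponential and nitrogen-limited windows, and
  a weighted combination of protein production and ATP (weight φ) when
  quiescent.  Growth is fixed to zero in lag, stationary and decay.
  The multiobjective quiescent problem is scalarized as
  `v_Prot + φ·v_ATP` with a single weight rather than solved
  lexicographically; φ is an estimable parameter.  "ATP production" is
  operationalized as flux through the ATP maintenance (hydrolysis)
  reaction.
- **Kinetic bounds, not kinetic rates.** Medium concentrations enter
  only through flux *bounds* (and through the product-coupling equality
  rows); within the bounds the LP chooses fluxes.  In the
  substrate-limited phases the optimizing objective drives uptake to
  its bound, so the bound-based and rate-based readings coincide at the
  optimum.
- **Product coupling.** Each fermentation product's secretion flux is
  pinned to instantaneous hexose transport through an equality row
  `v_Pj + k_Pj(v_Glx + v_F) = 0` inside the LP, keeping `v_Glx`, `v_F`
  as decision variables.  Acetate is the exception: it is coupled like
  a product during the growth phases and switches to forced mass-action
  consumption (`v_Ace = −k_ace·Ace`) when quiescent.  The switch is
  keyed to the phase schedule, not to a concentration trigger.
- **Proline.** Proline carries no assimilable nitrogen (it is not
  catabolized anaerobically); its exchange is excretion-only and is
  tied to hexose transport (`v_Pro = −α_Pro·(v_Glx+v_F)`) during
  stationary/decay.  Its medium dynamics are `dPro/dt = X_A·v_Pro`
  with no turnover-release term, so proline residues freed by protein
  turnover are not returned to the medium — a deliberate small nitrogen
  leak that mirrors the asymmetric treatment of proline in the
  phase-objective formulation.
- **Protein turnover.** After nitrogen exhaustion the protein pool
  (Prot, g/L) degrades at rate λ into extracellular amino acids that
  can be re-assimilated; quiescent amino-acid uptake bounds are the
  volumetric turnover supply divided by active biomass X_A (LP fluxes
  are per gDW).  Turnover (λ) and decay-phase death (k_death, k_decay)
  are kept as separate parameters with separate roles; nothing forces
  them equal.
- **Active vs viable biomass.** X_A (ferments) and X_V (divides and
  ferments) separate so that dry weight, OD and CFU data can all be
  described; X_V additionally declines through an ethanol Hill term
  with parameters (k_Edeath, n, k).

## Dynamic biomass equation

`Prot_content = A(1 − e^{B·YAN})` requires `B < 0` so the content
saturates at `A` on rich medium and falls to zero as YAN is exhausted;
a positive B would produce negative content, so the sign is enforced at
the interface.  mRNA is held proportional to protein
(`mRNA = Prot/RNA-to-Prot`), DNA is a fixed configured fraction, and
carbohydrate is the compensating pool that absorbs all remaining mass
(and any rounding during fitting).  The biomass pseudoreaction column
and its ATP coefficient (GAM) are rewritten in place; by default this
happens on every solve of every growth phase — with the persistent LP
backend a column update costs microseconds, so there is no reason to
restrict the rewrite to the nitrogen-limited window (a config switch
restores that behavior).  Per-gram polymerization costs shipped in the
default config (protein 30, RNA 4, carbohydrate 6.2, DNA 8 mmol
ATP/g) are placeholders of realistic magnitude, not curated values.

## The toy network

`build_toy_network` is a desk-scale stand-in for a genome-scale
reconstruction: two hexoses (with an isomerase), fermentative
(2 ATP/hexose), acetogenic (2 ATP) and respiratory (18 ATP) catabolism,
a glycerol overflow route, per-amino-acid synthesis (from hexose
carbon + ammonium) and degradation (to ammonium + CO2), gram-based
protein/carbohydrate/RNA/DNA pools, a rewritable biomass pseudoreaction
and a protein-accumulation sink that carries the quiescent-phase
protein flux.  Every metabolite declares an integer-ish carbon and
nitrogen count and every internal reaction balances both exactly, which
is what makes whole-simulation conservation audits possible without
formula parsing.

What it deliberately does *not* emulate: redox (NADH/NADPH) balancing —
the acetogenic route is therefore given the same ATP yield as
fermentation so it cannot act as a spurious high-yield overflow — and
pathway-level detail (one lumped reaction per route).  Tests passing on
the toy network validate the *framework* (phase switching, coupling,
turnover, conservation, estimation machinery), not any statement about
real yeast metabolism.

## Reference study conditions

The default parameters and initial state describe an anaerobic
wine-like batch: 1 M total hexose (~150 g/L plus a little sucrose),
~11 mM YAN, 0.05 g/L inoculum, 250 h horizon with phase switches at
4/55/65/200 h.  They were chosen once to produce a realistic
fermentation: growth to ~5 g/L set by nitrogen exhaustion, ~96% sugar
consumption with a residual at the end of decay, ~70 g/L ethanol, a
biomass yield near 0.12 g/g in the growth phase, and a CFU decline of
about an order of magnitude driven by ethanol.  The ethanol yield
coupling k_P = 1.55 mmol/mmol hexose is a process-wide compromise
(growth diverts carbon early, quiescent metabolism approaches the
theoretical 2).  NGAM (0.4 mmol ATP/gDW/h) is what arrests the
simulated fermentation when late-stage ATP supply falls below
maintenance — with substantially higher NGAM or lower inhibition
constants the batch aborts before t_F, which is the model's
"premature end of fermentation" behavior, surfaced as a loud
`SimulationError` rather than silently continued.

The synthetic-data generator samples this reference simulation at 12
time points for six observables (hexoses, ammonium, ethanol, active
biomass, protein), adds independent Gaussian noise with
`σ = max(cv·|y|, floor)` (floor = 5% of the observable's maximum times
cv, keeping σ positive at depleted signals) and emits replicates with
the true σ recorded.  It emulates measurement noise only — no
systematic errors, no missing data, no replicate correlation — so
recovery results bound what is achievable under ideal error models.

## Numerical choices

- **LP backend.** Two persistent GLPK problems per network structure
  (stage 1; stage 2 with |v|-split variables, an objective-floor row
  and 2n absolute-value rows).  Bounds, the biomass column, coupling
  rows and objectives are mutated in place with change detection, so a
  dFBA re-solve costs ~0.05 ms.  Stage 2 fixes the stage-1 optimum to
  1e-6 relative and minimizes Σ|v|; remaining degenerate ties are
  resolved by the simplex basis.  Because warm starts make tie-breaking
  history-dependent, every `simulate()` discards and rebuilds the
  backend (~1 ms), which makes repeated simulations bitwise identical —
  load-bearing for the exactness of the likelihood at the truth and for
  seeded-fit determinism.  A spurious infeasibility from a stale warm
  basis is retried from the standard basis; a genuinely infeasible
  phase LP gets one retry with 1e-9-scale bound slack and then aborts
  with a diagnostic listing the binding constraints.
- **Integration.** LSODA with per-phase restarts (rtol 1e-6,
  atol 1e-9 by default; 1e-4/1e-7 in the estimation inner loop, where
  the weighted-least-squares objective tolerates the extra noise).
  The trajectory is recorded at accepted steps; fluxes and `‖S·v‖∞`
  residuals are recomputed per record against the S matrix in force at
  that step.  Concentrations are clipped at zero inside the RHS and a
  substrate below 1e-12 mM has its uptake bound shut to avoid LP
  chattering near depletion.
- **Conservation bookkeeping.** An auxiliary state integrates net
  carbon import into cells (exchanges minus turnover release), and CO2
  is tracked explicitly, so total carbon (medium + CO2 + cells) is a
  linear conserved functional of the state — preserved to rounding by
  any linear multistep method, and therefore a sharp audit of the RHS
  sign conventions and stoichiometry rather than of integrator
  accuracy.  Biomass lost to decay keeps its carbon booked as
  cell-derived material (dead mass is not returned to the medium).
- **Estimation.** Differential evolution (seeded, Sobol
  initialization) over box bounds, followed by Nelder–Mead polish from
  the best population members — the LP-switching kinks in the
  objective make several short descents more robust than one long one.
  The turnover rate λ is searched in log10 space (it spans decades).
  Failed simulations score `1e10 + missing hours`, ranking partial
  failures smoothly.  Phase times, when estimated, are reparameterized
  as positive increments to enforce their ordering.  Bootstrap
  resampling draws individual replicate measurements uniformly with
  replacement, preserving dataset size; each resample leaves out
  ≈ 1/e ≈ 37% of records.
- **Flux ratios.** Trapezoidal integration on the stored solve points;
  dry weight in the integrals is X_A times the configured culture
  volume.  The growth window is [t_L, t_S) (exponential plus N-limited,
  lag excluded); the overall window is [t0, t_F] including lag.
  Phase-boundary records are stored once per adjacent segment, so each
  window integrates its own side of the flux discontinuity.

## Validation problem sizes

The shipped studies run a full 250 h reference batch (~280 LP-recorded
steps), compare the solver with a vertex-enumeration oracle on 20–25
random networks of ≤ 8 reactions, estimate the bootstrap leave-out
fraction from 1000 resamples of a 100-record dataset, and fit ten
seeded synthetic datasets (four free parameters each) for the recovery
study — sizes chosen so the whole validation runs in minutes on a
single CPU while still exercising every phase and module.

## Known limitations

- No redox or cofactor bookkeeping in the toy network; flux-ratio
  interpretation in terms of NADH/NADPH balance requires a real
  reconstruction loaded through the SBML reader.
- Single compartment, no CO2 off-gas partitioning, no temperature or pH
  effects; dissolved oxygen is consumed but never replenished.
- The quiescent-phase objective weight φ is identifiable only when
  protein production and ATP genuinely compete; on the toy network the
  turnover bounds dominate, so φ is kept small and fixed by default.
- The generic extension-table mechanism checks stoichiometric
  consistency only against declared element counts; it does not curate
  reaction content.
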