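# Methods

## The switch model

The core of the package is a two-variable model of the decision a glioma
cell makes between proliferating and migrating ("go or grow").  `M` is the
activity of miR-451, `A` the activity of the CAB39/LKB1/STRAD/AMPK
complex, and `G` the glucose input at the cell's location.  Each species
is produced autocatalytically with a saturating (Hill-type) bound and
represses the other:

    eps * dM/dt = G + k1*k2^2 / (k2^2 + alpha*A^2) - M
          dA/dt = S + k3*k4^2 / (k4^2 + beta*M^2)  - A

Time is measured in units of the complex's lifetime (the reference hour).
`eps` is the ratio of the degradation rates of the complex and of miR-451;
because miR-451 turns over much faster, `eps = 0.02` is small and `M` is
the fast variable, relaxing onto its nullcline within a fraction of an
hour while `A` adjusts on the hour scale.  Production is bounded
(`dM/dt < 0` whenever `M > G + k1`, `dA/dt < 0` whenever `A > S + k3`), so
trajectories with nonnegative initial data remain nonnegative and bounded.

With the reference parameters (`k1 = k3 = 4`, `k2 = k4 = 1`,
`alpha = 1.6`, `beta = 1`, `S = 0.2`) the equilibrium curve `M*(G)` is
S-shaped: a low-M (migratory) and a high-M (proliferative) stable branch
coexist between two saddle-node folds, which the continuation module
locates at `G = 0.399` and `G = 0.580`.  Quasi-statically raising glucose
flips the switch up only past the upper fold; lowering it flips back only
below the lower fold, producing the hysteresis loop: the cell's phenotype
depends on the *history* of glucose, not only its present level.  A cell
classifies as proliferative when `M` exceeds the threshold `M_th = 2`.

The glucose-deprivation experiment (normal 4.5 g/l medium versus reduced
0.3 g/l) is emulated by placing the switch on the upper branch at a
mono-stable high glucose level (`G_high = 0.7`, above the upper fold),
stepping glucose down by the factor 0.3/4.5, and letting the state relax;
the steady-state miR-451 falls by about 95%, consistent with the reported
reduction of more than 80%.  Because relaxation, not naive root-picking,
selects the low-glucose branch, the computation is history-consistent by
construction.

### Numerical treatment of the switch

* Equilibria: `A` is eliminated through its nullcline, the scalar residual
  in `M` is scanned on a dense grid (10^4 points across the production box
  `[0, G + k1]`, i.e. a resolution of 1e-4 of the box), sign changes are
  bracketed with Brent's method and polished by Newton steps to a residual
  below 1e-12; roots closer than 1e-8 are merged.  Stability comes from
  the eigenvalues of the analytic Jacobian.
* Continuation: equilibria are computed on a uniform `G` grid and folds
  located by bisection on the change in root count to |dG| <= 1e-4.  A
  fold-free (monotone) curve is reported with `fold_low = fold_high =
  None` rather than an error.
* Time integration uses LSODA with `rtol = 1e-8`, `atol = 1e-10`
  (1e-10/1e-12 where a trajectory serves as an oracle); the slow-fast
  structure at `eps = 0.02` is mild but the stiff-aware integrator also
  covers the `eps -> 0` consistency checks.

## The tissue model

Six fields live on the unit interval (reference length 1 cm; `x = 0` is
the tumor core, `x = 1` the far field): tumor cell density `n`, ECM
density `rho` (both relative to carrying capacity), MMP concentration
`P`, glucose `G`, and the per-location switch variables `M`, `A`.

* Tumor cells move only in invasion mode (`M < M_th`): random motility
  `D_n`, chemotaxis up the glucose gradient, haptotaxis up the ECM
  gradient, with a Lapidus–Schiller receptor law and a volume-filling
  factor: `J = -D_n dn/dx + n (1 - n) [chi G_x/(1+sigma_G G)^2 +
  h rho_x/(1+sigma_rho rho)^2]`.  The `(1 - n)` factor keeps the density
  below carrying capacity even where the velocity field is compressive;
  without it the reference run crowds cells past capacity at the front.
  In growth mode cells proliferate logistically at rate `r_growth = 0.1`/h
  and do not move — growth alone can never colonize empty territory,
  which is why the initial profile is compactly supported.
* ECM is degraded by MMP (`d_rho = 0.508`) and remodels logistically
  (`r_rho = 0.18`).
* MMP is secreted by invasive cells in contact with ECM (`a_P = 2.5`,
  gated by the invasion weight, configurable) and decays at `d_P = 0.18`;
  its small diffusivity keeps it localized near the secreting front.
* Glucose diffuses, is consumed at rate `lambda_G = 1.0` per unit cell
  density, and is replenished by injections into the far-field band of
  width 0.08 next to `x = 1`.  Each injection delivers a dose `g_in` per
  unit band length (total `0.08 * g_in`) spread over the 0.01 h pulse
  duration; pulses repeat every `tau` hours starting at `t = 0`.  An
  equal-dose continuous twin delivers `g_in / tau` per hour on the same
  band.
* The growth/invasion indicators are logistic sigmoids in `M` with width
  0.05 (half-weight exactly at `M_th`); the sharp indicators are recovered
  as the width tends to zero.

Boundary conditions are zero-flux for every field, so the injection source
is the only way glucose enters and the glucose budget closes exactly:
change in total G = injected − consumed, which the simulator tracks
step-by-step with the same quadrature used for the update.

### Initial conditions

The default scenario places a tumor plateau of height 1 with a smooth
compactly-supported cosine front on the left of the domain; ECM is intact
outside the tumor and reduced to 0.5 inside; there is no MMP; glucose is
uniform at `G0 = 0.1`.  The switch fields start at the history-consistent
equilibrium: the state reached by relaxing from the proliferative
normal-glucose culture branch to the ambient `G0`.  With the reference
parameters this is the migratory branch (cells begin invasive, `M < M_th`
everywhere); with weakened miR-451 inhibition (low `alpha`) or
strengthened AMPK inhibition (high `beta`) the proliferative branch
remains stable down to `G0` and cells begin — and stay — proliferative,
which is exactly the mechanism behind the inhibition-sweep predictions.

### Calibration of unprinted coefficients

The dimensionless transport coefficients (`D_n`, `D_P`, `D_G`, `chi`,
`h`), the taxis saturation constants, the initial tumor width and the
initial glucose level are not fixed by the reference parameter tables.
They were set from physical magnitudes (cell motility ~1e-9 cm^2/s, MMP
diffusion small, glucose transport fast enough that far-field pulses reach
the tumor within a fraction of the injection period) and then calibrated,
once, so that the reference periodic-injection experiment reproduces the
reported regime: the tau = 10 h, g_in = 5 schedule produces exactly three
completed growth–invasion cycles in 100 h, the equal-dose constant twin
stays cycle-free and grows less, tau = 50 h with g_in = 5 starves the
switch into constant invasion, and lowering `alpha` or raising `beta`
locks the tumor proliferative and small.  The frozen values are the
`PDEParams` defaults.  They are effective tissue-scale values, not
measured constants; in particular `D_G` exceeds the molecular diffusivity
of glucose because pulse transport across a 1 cm domain within hours is a
prerequisite for the cycling phenomenology.

## Time stepping

Each accepted step applies Strang splitting: half a transport step, a full
local-reaction step, half a transport step.  Tumor advection–diffusion is
explicit (first-order upwind taxis, central diffusion) under a 0.9
advective CFL cap; MMP and glucose diffusion are Crank–Nicolson with a
tridiagonal solve (unconditionally stable, exactly conservative); the six
local reactions are advanced with vectorized RK4 substeps of at most
5e-3 h — the fastest local rate is `1/eps = 50`/h, well inside RK4's
stability region at that substep.  Steps are aligned to injection-pulse
edges so the source is constant within any step, making the injected-dose
bookkeeping exact.  The step size starts at 1e-3 h, is halved whenever a
sub-step produces negative, non-finite or diverging fields (down to
`dt_min`, after which the run is flagged partial), and grows by a factor
1.2 after five clean steps up to `dt_max = 0.01` h.  The model is fully
deterministic: identical configurations produce byte-identical outputs.

Problem sizes: the production grid is 100 cells (`dx = 0.01`) and the
reference horizon 100 h; the convergence checks run a 30 h horizon
(within the initial invasion epoch, before any threshold crossing) and
halve `dx` and `dt`, changing the final tumor population by less than 2%
and 1% respectively.  Over the full cycling horizon the final population
is a discrete functional of near-grazing threshold crossings, so `dx`
refinement can shift a growth burst and change the total by a few
percent; this is a property of the model, not of the scheme, and is why
convergence is certified on the smooth epoch.

## Phase classification and cycle counting

The population-level phase at time `t` is growth if the tumor-weighted
mean of `M` (weight `n`, floored at 1e-6 to avoid empty-support division)
exceeds `M_th`, else invasion.  A completed cycle is one full
invasion → growth → invasion alternation.  Because the mean can graze the
threshold, runs shorter than a 0.5 h debounce dwell are merged into their
longer neighbor before counting; the count is then invariant to output-
cadence refinement.  (The alternation count on the tumor-weighted mean
agrees qualitatively with counts on the total-population or total-AMPK
series; the mean-M convention is the package's single normative choice.)

## What the synthetic scenarios do and do not show

All experiments are self-generated: the fixture library encodes the
canonical setups (equilibrium continuation, deprivation protocol,
periodic injections, the constant-supply twin, the inhibition sweeps, the
period/dose grid) with no external data.  They demonstrate the internal
consistency of the model — bistability, hysteresis, pulse-locked
switching, the fluctuation growth advantage — under idealized 1-D
geometry, deterministic dynamics, a single nutrient, and no host tissue,
vasculature, cell–cell adhesion or stochasticity.  Passing tests say
nothing about real glioma kinetics beyond what the model class itself can
say; parameter values for the tissue-scale coefficients are effective and
partly calibrated to the reported phenomenology rather than measured.

## Known limitations

* The proliferative regime is support-locked: because growth is logistic
  and movement is invasion-gated, a tumor that never leaves growth mode
  cannot expand beyond its initial support.  Consequently the abundant-
  dose schedule (tau = 10 h, g_in = 30), which locks proliferation within
  the first hours, ends *smaller* than the cycling g_in = 5 schedule —
  the dose-monotonicity of the final population holds at sparse
  injections (tau = 50 h) but not at dense ones.  The same lock is what
  makes the low-`alpha` and high-`beta` tumors small, so within this model
  class the two reported orderings cannot both hold at dense injections.
* First-order upwinding of the taxis terms trades formal accuracy for
  positivity; fronts are numerically diffused over a few cells.
* The debounced cycle count is a discrete functional of a continuous
  trajectory; near-grazing threshold crossings make it sensitive to
  parameter perturbations of a few percent (it is exactly reproducible
  for a fixed configuration).
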