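# Methods

## Models and assumptions

All seven dynamical systems are deterministic mass-action ODE models in a
concentration unit U (~10 nM) and time unit T (~1 min). Enzyme and substrate
totals are comparable, so enzymatic steps are written as elementary
binding/dissociation/catalysis reactions, never as Michaelis-Menten rate laws.
De-modifying enzymes (phosphatases, the de-ubiquitinase) act as mass-action
catalysts whose concentration is absorbed into the first-order rate constants
`k_dm1`, `k_dm2`, `k_dp`, `k_du`. Models are defined as plain-text rate-law
expressions compiled once into scalar Python functions; the same expressions
are serialized to the restricted `.ode` dialect, which makes the round trip
exact by construction.

Free species are algebraic: `A = A_T - C - C_M` (basic motif),
`[Clb] = [ClbT] - [Clb:Sic]`, `[APC] = [APCT] - [APC:MCC]`, and so on. These
expressions are clamped at zero inside the right-hand side (`max(x, 0)`), a
guard against transient solver overshoot only - steady-state candidates that
actually sit on a clamped boundary are rejected as inadmissible during root
finding. Two models keep a state-space conservation law (the inhibitor total
of the basic and simplified motifs); all analysis on them is done on the
reduced system with one variable eliminated through the conservation
identity, which keeps the Jacobian nonsingular.

The TQSSA closure (used by the two-variable reduction and the MCC-APC model)
is the smaller root of the tight-binding quadratic
`C^2 - (A_T + I_hat + K_m)C + A_T*I_hat = 0`, the only root satisfying
`0 <= C <= min(A_T, I_hat)`; it is evaluated in the cancellation-free form
`2 a i / (b + sqrt(b^2 - 4 a i))`.

In the doubly phosphorylated CKI models the second phosphorylation flux is a
pure sink: the SicPP form is degraded so fast it never appears as a pool, so
the Sic1 total excludes it by construction. The composite constants
`k_a*N_T` and `k_in*[CAPP]` are stored exactly as catalogued products and
never split. `X_tens` (fraction of centromeres under bipolar tension) is an
external control parameter in all scenarios; kinetochore attachment kinetics
are not modelled.

## Reconstructed totals for the mitotic checkpoint

The APC and Mad2 totals are not part of the published rate-constant
catalogue. The defaults `APC_T = 1 U`, `Mad2_T = 2 U` are an assumption,
reconstructed by requiring the MCC-APC model to reproduce three published
anchors simultaneously: the disengagement threshold (computed 0.957 against
~0.97), the re-engagement threshold (0.893 against ~0.89) and the in-vitro
release lag (46.7 T against ~45 T). A Mad2 pool of 1 U admits no bistability
in `X_tens` at all, and larger pools push both thresholds toward 1 while
stretching the lag past 100 T, so the choice is tightly constrained. Both
totals are ordinary parameters and can be overridden everywhere.

With these totals the cyclin-B-coupled model's disengagement threshold is
0.940, slightly below the 0.95 cut used as the default operationalization of
"sensitivity" in the robustness scans; that cut is therefore exposed as a
parameter of `sensitivity_irreversibility_region`.

## Numerical choices

* **Steady states**: multistart Newton (scipy `hybr`, 64 starts by default)
  from randomized admissible states honouring the totals; roots accepted at
  max-norm residual < 1e-9 U/T, deduplicated at relative tolerance 1e-6,
  sorted by free-activator fraction. Deterministic given the seed (default 0).
* **Stability**: eigenvalues of a central finite-difference Jacobian of the
  reduced system (step scaled to state magnitude, falling back to one-sided
  differences at the nonnegativity boundary). Stable means every real part
  below -1e-6 T^-1; roots with a real part inside +-1e-6 are flagged
  degenerate rather than silently classified. Boundary attractors (several
  exact zeros, e.g. the disengaged state at full tension) defeat
  finite-difference spectra; where a start state matters, stability falls
  back to the integration oracle (perturb, relax, compare).
* **Fold detection**: no pseudo-arclength continuation - for these S-shaped
  response curves it suffices to (a) bisect root-count changes on a sweep
  grid, or (b) continue the occupied branch with warm-started Newton steps
  (secant extrapolation; on failure the guess is relaxed by a short
  integration before one retry) and bisect where the branch is lost. Both
  locate folds to relative parameter tolerance 1e-4 and agree to ~1e-3.
  A root-count jump larger than 2 between adjacent grid values triggers one
  4x grid refinement, then an error.
* **Integration**: LSODA at rtol 1e-9/1e-10, atol 1e-11/1e-12; relaxation to
  steady state proceeds in geometrically growing time chunks until the
  residual is below tolerance, with a timeout flag rather than an exception.
* **Classification**: a state is engaged when the free-activator fraction is
  at most 0.05 and disengaged at 0.15 or more; unstable roots are labelled
  intermediate. These bands are labelling conventions, validated against the
  branch structure of all six presets; diagram branches take the label of
  the zero-signal state they connect to.

## Schedules, scenarios and their conventions

Event schedules are piecewise-constant parameter switches with integrator
restarts. When an event moves a conserved total, the difference is booked
against the free pool (the eliminated variable), clamped at zero with a
warning - an instantaneous bolus. Note that a large bolus is a genuine
perturbation: restoring the inhibitor total of the basic motif in one step
can kick the state across the separatrix and re-engage the switch, whereas a
quasi-static restore (a staircase, or the piecewise-linear hysteresis
protocol, where the total moves as a continuous source term on the free
pool) leaves it disengaged, as the steady-state analysis predicts.

* **G1/S cycle**: the cyclin totals become dynamical variables driven by a
  synthesis/degradation program (both syntheses on at t = 0; Cln synthesis
  off and degradation on at t = 30 T; Clb synthesis off and degradation up
  at t = 50 T). The cyclin rates are not catalogued; the defaults
  (`ks_cln = 0.025`, `ks_clb = 0.035 U/T`, `kd_cln = 0.15`,
  `kd_clb = 0.01 -> 0.15 T^-1`) were chosen once so that the projected
  (`[ClbT]`, `[ClnT]`) path crosses the control-plane V exactly once on the
  way up and re-enters the engaged region only after division. The G1/S
  transition time is the first moment free Clb-kinase exceeds half the Clb
  total (a declared convention). Because the fold-point ghost and Sic1
  turnover impose a real kinetic delay, the *time-course* label change lags
  the geometric fold crossing by ~15 T at these ramp speeds; the
  crossing-consistency property (label flip within 1 T of the crossing)
  holds in the quasi-static protocol, not in the finite-speed time course.
* **In-vitro release**: engaged steady state at zero tension, `X_tens`
  stepped to 1; the lag is the first time functional MCC
  (`[MCCT] - [MCCU]`) falls to the APC total.
* **In-vivo release**: tension staircase 0 -> 1 -> 0 on the cyclin-B model.
  The default hold at full tension is 80 T because release is sluggish
  (~47 T lag); anaphase onset is the moment securin falls below 25% of its
  engaged level (declared convention; the disengaged securin floor is ~12%
  of the engaged level at the default totals, so the traditional 10% cut
  never fires here).

## Robustness scans

`scan_disengage_threshold` perturbs one rate constant at a time over a
log-spaced fold range (default 2-fold either way) and recomputes the
disengagement threshold by branch continuation. At the reconstructed totals
the minimum over 2-fold scans of the five core constants is ~0.90 (worst
cases: doubling `k_cat`, halving `k_du`), not 0.95: rapid de-ubiquitination
is itself the source of sensitivity, so halving `k_du` necessarily erodes
the threshold. The 0.95 floor therefore holds over roughly 1.3-fold scans
here, and the scan range is a parameter rather than a constant.

`sensitivity_irreversibility_region` applies two criteria to the
cyclin-B-coupled model - threshold above the sensitivity cut, and no
re-engagement fold anywhere in `X_tens` in [0, 1] - and reports the fraction
of perturbed points passing both. The region is restricted (fraction well
below 1 over 4-fold scans), consistent with the mechanism being sensitive
and irreversible but not robustly so.

The partial-processivity variant branches the catalytic step of the tight
complex: a fraction `p` releases the doubly modified product directly. At
`p = 0` it reduces exactly (bit-for-bit) to the basic motif, and bistability
at the neutral point survives `p = 0.2`. In fact, at these rate constants
bistability survives all the way to `p = 1` (verified by the integration
oracle from both sides): strong sequestration of the enzyme by the
unmodified inhibitor sustains the double-negative loop even without a
distributive release step. Distributivity widens the bistable region; it is
not an absolute requirement at this operating point.

## What the scenarios do and do not show

The synthetic schedules emulate the *signals* of the cell cycle (cyclin
synthesis programs, spindle tension) as clean parameter programs. They do
not model attachment kinetics, cell growth, stochastic fluctuations at
10 nM-scale copy numbers, or the transcriptional layers around the switches,
so passing tests establish the dynamical competence of the switch motifs -
bistability, thresholds, irreversibility, lags - not quantitative agreement
with any particular cell.

## Problem sizes

The test suite and the acceptance script use sweep grids of 10-15 points
with root-count bisection to relative tolerance 1e-4, control planes of
20 x 20 cells, 16-64 Newton starts per parameter point, and robustness scans
of 3-5 points per rate constant; the full suite runs in under a minute on
one CPU. All tolerances above are package defaults and can be overridden
per call.

## Known limitations

* Fold detection assumes fold-only bifurcation structure (correct for these
  models); Hopf or global bifurcations would be misread as branch loss.
* `find_steady_states` can return an empty list at degenerate parameter
  corners (e.g. exactly full tension, where the disengaged state sits on the
  nonnegativity boundary); the integration oracle is the reliable route to
  such attractors.
* The multistart root count is probabilistic in principle; the default
  start counts were validated against quasi-static integration on all six
  presets, but pathological parameter sets could hide a narrow basin.
* The `.ode` dialect is deliberately restricted (par/init/aux/derivative/
  done); XPPAUT option lines are skipped with a warning, and aux definitions
  are usable inside rate laws, which XPPAUT proper would express as fixed
  quantities.
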