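# Methods

## Model family and assumptions

The package implements four nested ODE models of antigen-driven T cell
activation (see README for the equations). Shared assumptions: antigen
stimulation β is an exogenous parameter, not a state (no pathogen
dynamics); IL-2-dependent proliferation is linear in IL-2; APCs are not
modelled explicitly — their effect is folded into β; there are no induced
Tregs, no memory compartment, no homeostatic peripheral division (the
thymus, via the renewal rates N₀ and λN₀, is the only source of naive
cells and resting Tregs); and Tregs suppress activated T cells by direct
contact (rate γ), independent of APC conjugation. Time and all rates are
dimensionless; no unit-conversion layer is provided.

The canonical parameter set ships as `data/table1.toml`. The death rate of
the naive compartments defaults to **g = 0.1** (equal to the activated-cell
death rate b). g only enters through the activation map k = βN₀/(g+β);
every reduced-system result (k₋, c₋, k_i, k_s, λ_th) is g-independent, and
all g-dependent outputs (β_i, β_s, CSV provenance) report the g used.

## Equilibrium analysis

Equilibria are computed by exact elimination rather than blind search:
IL-2 balance gives I(T); for the Treg model the Treg balance gives
R = λk/(b − εaI) and the IL-2 balance T = I(eR+f)/(d − eI), leaving a
quintic in I whose coefficients are assembled by polynomial arithmetic.
Candidate roots are polished by Newton iteration (hybr, xtol 1e-14) and
any candidate whose residual exceeds 1e-9 relative to the state scale is
discarded — this removes the spurious roots introduced by clearing the two
denominators. When λk = 0 the Treg balance factorizes and the two branches
(R = 0, and I pinned at b/(εa)) are enumerated directly. Duplicates are
merged at 1e-6 relative tolerance.

Branch naming follows position along T: T1 low/trivial, T2 threshold
(unstable), T3 fratricide-saturated, T4 Treg-controlled, T5 the
non-physical branch. One bookkeeping subtlety: for any λk > 0 the
saturated branch has a slightly negative Treg component (I sits near d/e
there, beyond the b/(εa) pole), so T3 is flagged non-physical while
keeping its name; only T-negative branches are T5. With this convention
the reduced Treg model has 5 real equilibria below the fold and 3 above,
with a single transition.

Stability is classified from the analytic Jacobian (hand-derived, verified
against sympy differentiation and finite differences in the tests):
stable (all real parts < 0), unstable (all > 0), saddle (mixed), and
marginal when any |Re| < 1e-9 — bifurcation points sit exactly there, and
a stable/unstable call at that resolution would be noise.

An independent multi-start oracle (seeded scrambled-Sobol starts, half of
them cubed towards the origin where the low-population roots live, plus
the zero start) cross-checks the elimination route; the closed-form
equilibria of the minimal model agree with it to better than 1e-12
relative on a hundred randomized parameter sets.

### Threshold formulas

The fold of the influx-driven T/IL-2 system, k₋ = (adf/e²)(1−√(1−be/ad))²,
is exactly the smaller root of the discriminant of
(ad−be)T² + (ke−bf)T + kf in k; the fratricide threshold
c₋ = (√(ad)−√(be))²/f likewise solves (be+cf−ad)² = 4cebf. Both identities
are verified algebraically in the tests and numerically against fold
continuation (dual-oracle requirement, 0.1% tolerance; observed agreement
is at rounding level). Note a scaling property used as a test invariant:
(d, e) → (s·d, s·e) maps k₋ → k₋/s (and leaves c₋ unchanged), as
substitution into the discriminant shows.

## Continuation

`continue_branch` is a pseudo-arclength predictor–corrector. The tangent
is the SVD null vector of the bordered Jacobian [J_x | J_α]; the corrector
solves the system augmented with orthogonality to the tangent. States are
continued in per-step rescaled units (component scale max(|x|, 1),
parameter scale the range width) so that branches spanning several orders
of magnitude — the saturated branch sits near 3·10⁴ cells — keep making
progress; step size adapts between 1e-7 and 0.15 (scaled), growing 1.3×
on success and halving on corrector failure. Branches are seeded from the
polynomial equilibria on a 7-point parameter grid; duplicates are dropped
by point-to-polyline distance in signed-log state coordinates, which is
well defined on folded curves. Branch escape beyond the state cap
(default 1e6 cells) truncates the branch and sets a flag.

Folds are detected by a sign change of det J between accepted steps and
refined by Newton on the augmented system (G = 0, det J = 0); Hopf points
by a sign change of the leading complex-pair real part, refined by
bisection in the parameter with Newton-corrected states. Detection
tolerance for "complex" is |Im| > 1e-8.

## Response detection and thresholds

The authoritative regime classification is trajectory-based, matching how
the regime diagrams are constructed: integrate the reduced system from the
all-zero state under constant k and ask what happens. "Zero initial
conditions" means every compartment empty — in the full model the naive
compartments then charge towards their steady states; the pre-charged
homeostatic start is available as an option.

A response counts as **initiated** when the trajectory either

* **escapes**: peak T exceeds max(10 × T_ref, 1 cell), with T_ref the
  largest sub-saturated equilibrium population; or
* **sustains an oscillation**: post-transient (last 50% of the horizon)
  peak-to-peak amplitude above 5% of the mean level, with the amplitude
  not collapsing (last-quarter/previous-quarter ratio > 0.5) and at least
  3 peaks (or amplitude > 50% of the level for slow relaxation cycles).

The escape test alone is not a reliable λ_th detector: the transient
burst height decays continuously with λ, so a pure peak criterion is
sensitive to its factor (moving λ_th by ±20% when the factor is halved or
doubled). The oscillation clause ties the predicate to the existence of
the limit-cycle attractor, which appears and disappears at sharp
bifurcation values; with it, halving or doubling every detection threshold
moves λ_th by < 1e-5. Verdicts flagged ambiguous — few peaks, or an
amplitude-collapse ratio between 0.5 and 0.97 (a slowly damped spiral
near the Hopf point) — trigger horizon doubling from 2000 up to 8000 time
units before the verdict is accepted.

**k_i** and **k_s** are located by bisection on this binary outcome
(relative tolerance 1e-3); **λ_th** by bisection on "some k initiates"
(absolute tolerance 1e-5), probing fold-guided activation rates
k_fold·(1+δ), δ ∈ {1e-3 … 3}, since the oscillatory window — when it
exists — opens at the fold. Each is cross-checked against the
equilibrium-structure landmarks: k_i against the fold of the low branch
(bisection on the equilibrium count), k_s against the upper Hopf point of
the T4 branch, and λ_th against the λ where fold and Hopf merge
(`lambda_th_eigen`). Agreement is ≈ 0.05% for k_i, ≈ 0.8% for k_s (the
trajectory route sees slightly-damped ringing just above the Hopf point;
deviations above 1% are logged as diagnostics, with the trajectory result
authoritative), and < 2e-5 for λ_th. For the canonical parameters both
routes give λ_th = 0.01184.

Limit-cycle properties (envelope T_min/T_max, period from mean inter-peak
spacing) are measured from post-transient trajectories — deliberately a
measurement, not a boundary-value computation: cycle continuation and
Floquet analysis are out of scope. Periods range from ≈ 244 down to
≈ 93 time units across the λ = 0.006 window, with both envelope maximum
and period monotonically non-increasing in k.

## Simulation

`solve_ivp` with LSODA, rtol 1e-8 / atol 1e-10, restarted at every
stimulation-schedule breakpoint so β-discontinuities never straddle a
step. Default horizon 2000 time units with 4001 output samples. Unlimited
proliferation (a real outcome of the models without fratricide) is a
terminal event at a configurable cap (default 1e6 cells) labelling the
trajectory rather than a solver failure. Treg depletion is modelled as
clearing the resting-Treg pool at the window start and withholding a
fraction (default all) of its renewal during the window; fractional
variants are options.

## Design choices that were genuinely open

* **Trajectory vs bifurcation definition of k_i/k_s**: both are computed;
  the trajectory definition is authoritative because the regime coloring
  of the diagrams is trajectory-derived. Their near-coincidence is itself
  a result the tests assert.
* **Initiation predicate**: escape-or-sustained-oscillation, as motivated
  above.
* **g**: value not derivable from the reduced analysis; fixed at 0.1 and
  surfaced everywhere it matters.
* **Randomized robustness sets**: parameter perturbations are log-uniform
  within a factor of 2 of the canonical values, constrained to ad > be —
  wide enough to exercise the algebra, narrow enough that every set stays
  in the biologically sensible regime the formulas address.
* **Problem sizes**: dual-oracle checks use 100 (root finding) and 20
  (continuation) random sets; regime scans use 25-point log grids in k and
  40-point count scans; these sizes make every statistical statement in
  the test suite reproducible in seconds to a few minutes on one CPU.

## Limitations

* β piecewise-constant only; smoothly varying antigen loads are not
  representable.
* Limit-cycle periods/envelopes are sampled at finite output resolution
  (0.5 time units by default); sub-sample peak interpolation is not done.
* The regime map inherits the 1e-3 bisection resolution of k_i/k_s; very
  close to λ_th the window is narrower than the detection resolution and
  classification there is reported as boundary/ambiguous rather than
  forced.
* No two-parameter continuation (the λ_th curve in other parameters is
  found by repeated one-parameter analysis), no basin-of-attraction
  mapping beyond the zero-initial-condition probe, no stochastic or
  spatial effects.
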