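# tregdyn

Dynamical-systems analysis of immune activation by conventional T cells
(Tconv), regulatory T cells (Tregs), and IL-2 — a model family in which
self and nonself antigens are **not** structurally distinguished: whether a
stimulus triggers an immune response is decided purely by quantitative
thresholds on antigen stimulation and on the homeostatic balance between
naive T cells and resting Tregs.

The package is for modellers and systems immunologists who want to
reproduce, probe, or extend this class of ODE models: it provides the
model right-hand sides, closed-form equilibria and thresholds, numerical
bifurcation diagrams (pseudo-arclength continuation with fold/Hopf
detection), limit-cycle scans, regime classification, and scenario
simulations (antigen clearance, Treg depletion), both as a Python library
and as a `tregdyn` command-line tool.

## The models

Four nested ODE models share one parameter set (all rates dimensionless):

1. **Activated T cells and IL-2** — `model1`:

       dT/dt = a I T − b T
       dI/dt = d T − e I T − f I

   Activated T cells (T) secrete IL-2 (I) and proliferate on it. The
   system has the trivial steady state (0, 0) and a threshold saddle
   (T₂, I₂) = (bf/(ad−be), b/a), positive iff the clone-quality condition
   **ad − be > 0** holds. Above the saddle's stable manifold the clone
   proliferates without bound.

2. **Naive compartment and antigen stimulation** — `model4` adds naive
   T cells N with thymic renewal N₀, death g, and activation β:
   `dN/dt = N₀ − gN − βN`, with `+βN` feeding T. The steady-state
   activation rate is **k = βN₀/(g+β) < N₀**. Equilibria exist only for
   k below the fold **k₋ = (adf/e²)(1 − √(1 − be/ad))²**; initiation of a
   response requires k > k₋, hence N₀ > k₋ and β > g·k₋/(N₀−k₋).

3. **Fratricide** — `model10` adds activation-induced cell death −cT².
   For c below **c₋ = (√(ad) − √(be))²/f** a large saturated equilibrium
   T₃ caps the response. The model is bistable in k — once initiated, the
   response persists even at k = 0 (hysteresis).

4. **Tregs** — `model13` adds resting Tregs (renewal N̂₀ = λN₀, same
   activation β) and activated Tregs R that proliferate on IL-2 at
   relative rate ε, suppress T at rate γ, and consume IL-2:

       dT/dt = a I T − b T − c T² − γ R T + β N
       dR/dt = ε a I R − b R + β N̂
       dI/dt = d T − e I (T + R) − f I

   The reduced system `reduced13` replaces the naive compartments by their
   steady-state influxes k and k̂ = λk and carries the full bifurcation
   structure.

## The headline result

For the canonical parameters (a=0.4, b=0.1, c=10⁻⁵, d=0.01, e=0.01, f=1,
γ=0.1, ε=0.6, N₀=4) the reduced Treg model organizes immune outcomes into
three regimes of the activation rate k:

* **subcritical** (k < k_i): the response never initiates;
* **effective oscillatory** (k_i < k < k_s): a stable limit cycle of
  repeated proliferation bursts — an efficient immune response;
* **over-suppressed** (k > k_s): after an initial burst the system is
  damped into a small chronic equilibrium T₄ by over-activated Tregs.

k_i is the saddle-node where the low equilibrium branch vanishes, k_s the
Hopf point where T₄ stabilizes. Raising the relative Treg renewal λ closes
the window until the two merge at **λ_th**; for λ > λ_th no stimulation of
any strength can initiate a response. Unlike the fratricide-only model,
the Treg model has no hysteresis: clearing the antigen always returns the
system to homeostasis, and depleting resting Tregs during chronic
over-suppression transiently restores the response.

## Worked example

```
$ tregdyn lambda-th
lambda_th = 0.0118365  (method=trajectory, g=0.1)

$ tregdyn k-thresholds --lam 0.006
k_i = 0.850983  k_s = 3.48942  (fold 0.850548, Hopf 3.46176)
```

With λ = 0.006 (below λ_th ≈ 0.01184) the effective window spans
activation rates 0.851–3.489: stimulation mapping into it produces
sustained oscillations, e.g. at k = 1 the bursts reach ≈ 2.3·10³ cells
every ≈ 244 time units, shrinking to ≈ 82 cells every ≈ 93 time units near
k = 3.3 (stronger stimulation co-activates more Tregs, which cut each
burst earlier). At λ = 0.02 > λ_th the same probes find no response at any
k: the immune system is blind to this antigen — operationally, it is
"self". The `fold`/`Hopf` values are the independent eigenvalue-based
cross-check of the trajectory-derived thresholds.

Other entry points:

```
$ tregdyn equilibria --model reduced13 --k 0.5 --lam 0.006 --out eq.csv
$ tregdyn bifurcate --model reduced13 --range 0:4.5 --lam 0.006 \
      --out branch.csv --plot diagram.svg
$ tregdyn simulate --model model13 --beta-schedule "0:600:0.06,600:4000:0" \
      --t-end 4000 --out clearance.csv
$ tregdyn figure fig5b --outdir figures/
```

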