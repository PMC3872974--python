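"""Time-course integration and the scenario experiments.

Trajectories are integrated with LSODA (stiff-capable, adaptive) and
restarted at every stimulation-schedule breakpoint so discontinuities in
beta(t) never cross an integrator step. Unlimited proliferation — a real
outcome of the models without fratricide — is handled as a terminal
divergence event at a configurable population cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import equilibria as eqmod
from .models import get_model, rhs_model13
from .params import ParameterSet
from .schedule import StimulationSchedule

__all__ = [
    "Trajectory", "ResponseConfig", "ResponseSummary",
    "integrate", "detect_response",
    "scenario_ag_clearance", "scenario_treg_depletion",
    "homeostatic_state",
]

DIVERGENCE_CAP = 1e6


@dataclass
class Trajectory:
    """Sampled solution of one model run."""

    model_id: str
    t: np.ndarray
    y: np.ndarray  # shape (dim, len(t))
    events: list[tuple[float, str]] = field(default_factory=list)
    diverged: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        return get_model(self.model_id).names

    def component(self, name: str) -> np.ndarray:
        return self.y[self.names.index(name)]

    @property
    def T(self) -> np.ndarray:
        return self.component("T")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t} |
                            {n: self.y[i] for i, n in enumerate(self.names)})


def homeostatic_state(model_id: str, p: ParameterSet,
                      beta: float = 0.0) -> np.ndarray:
    """The resting steady state: naive compartments charged, no activity."""
    names = get_model(model_id).names
    vals = {"N": p.N0 / (p.g + beta), "Nhat": p.lam * p.N0 / (p.g + beta),
            "T": 0.0, "R": 0.0, "I": 0.0}
    return np.array([vals[n] for n in names])


def integrate(model_id: str, p: ParameterSet,
              schedule: StimulationSchedule | None = None,
              t_span: tuple[float, float] = (0.0, 2000.0),
              init=None, k: float | None = None, lam: float | None = None,
              n_samples: int = 4001, rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA",
              divergence_cap: float = DIVERGENCE_CAP) -> Trajectory:
    """Integrate a model over ``t_span``.

    Full models take a piecewise-constant ``schedule`` for beta (defaulting
    to constant ``p.beta``); reduced models take a constant activation rate
    ``k``. ``init`` defaults to the all-zero state, the convention used for
    regime probing (the naive compartments then charge up towards their
    steady states). Integration halts with a ``divergence_cap`` event when
    any component exceeds the cap, labelling unlimited proliferation.
    """
    info = get_model(model_id)
    lam = p.lam if lam is None else lam
    pp = p.replace(lam=lam)
    t0, t1 = map(float, t_span)
    if init is None:
        y0 = np.zeros(info.dim)
    else:
        y0 = np.asarray(init, dtype=float)
        if y0.shape != (info.dim,):
            raise ValueError(f"init must have length {info.dim}")
        if np.any(y0 < 0):
            raise ValueError("initial state must be nonnegative")

    if info.drive == "k":
        if k is None:
            raise ValueError(f"{model_id} requires k")
        pieces = [(t0, t1, float(k))]
        events_label = None
    else:
        if schedule is None:
            schedule = StimulationSchedule.constant(pp.beta, t1, t0)
        if not schedule.covers(t0, t1):
            raise ValueError("schedule does not cover the integration span")
        cuts = [t0] + schedule.breakpoints(t0, t1) + [t1]
        pieces = [(a, b, schedule.beta_at(a)) for a, b in zip(cuts, cuts[1:])]
        events_label = "beta_change"

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    events: list[tuple[float, str]] = []
    diverged = False
    t_grid = np.linspace(t0, t1, n_samples)

    for i, (a, b, drive) in enumerate(pieces):
        if i > 0 and events_label:
            events.append((a, events_label))
        fun = info.rhs_ivp(pp, drive)

        def hit_cap(t, y):
            return float(np.max(y) - divergence_cap)

        hit_cap.terminal = True
        hit_cap.direction = 1.0
        t_eval = t_grid[(t_grid >= a) & (t_grid <= b)]
        if t_eval.size == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(fun, (a, b), y0, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, events=hit_cap)
        if sol.status == -1:
            raise RuntimeError(
                f"integrator failed at t={sol.t[-1] if sol.t.size else a}: "
                f"{sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        if sol.status == 1:  # divergence event
            t_ev = float(sol.t_events[0][0])
            events.append((t_ev, "divergence_cap"))
            diverged = True
            break
        y0 = sol.y[:, -1]

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return Trajectory(model_id=model_id, t=t[keep], y=y[:, keep],
                      events=events, diverged=diverged)


# ---------------------------------------------------------------------------
# response detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseConfig:
    """Operational definition of an initiated immune response.

    A response counts as initiated when the activated T cell trajectory
    either escapes far above the small-branch equilibria (a proliferation
    burst: peak above ``escape_factor`` times the largest sub-saturated
    equilibrium and above ``escape_floor`` cells) or settles into a
    sustained oscillation (post-transient peak-to-peak amplitude above
    ``osc_rtol`` of the mean level and not collapsing). The headline
    thresholds are deliberately coarse: regime boundaries are dynamical
    and the classification is insensitive to doubling or halving them.
    """

    escape_factor: float = 10.0
    escape_floor: float = 1.0
    transient_frac: float = 0.5
    osc_rtol: float = 0.05
    min_peaks: int = 3
    decay_ratio: float = 0.5
    saturated_gap: float = 100.0  # T3 is this factor above the next branch


@dataclass(frozen=True)
class ResponseSummary:
    initiated: bool
    escaped: bool
    sustained_oscillation: bool
    peak_T: float
    n_oscillation_peaks: int
    T_max: float
    T_min: float
    period: float
    T_ref: float
    ambiguous: bool = False


def _small_branch_max(model_id, p, k, lam):
    """Largest equilibrium T below the saturated branch (reference scale
    for the escape test)."""
    pts = [q for q in eqmod.find_equilibria(model_id, p, k=k, lam=lam)
           if q.T >= 0]
    ts = sorted(q.T for q in pts)
    if not ts:
        return 0.0
    if len(ts) >= 2 and ts[-1] > 100.0 * ts[-2]:
        ts = ts[:-1]
    return ts[-1]


def detect_response(traj: Trajectory, config: ResponseConfig | None = None,
                    T_ref: float | None = None,
                    p: ParameterSet | None = None,
                    k: float | None = None,
                    lam: float | None = None) -> ResponseSummary:
    """Classify a trajectory as initiated / oscillatory / quiescent.

    ``T_ref`` (the largest sub-saturated equilibrium population) can be
    passed directly; otherwise it is computed from ``p`` and the drive.
    The trajectory must be long enough that the transient window leaves at
    least a handful of samples.
    """
    cfg = config or ResponseConfig()
    if T_ref is None:
        if p is None:
            raise ValueError("provide either T_ref or p (plus k for reduced models)")
        model_id = traj.model_id
        if get_model(model_id).drive == "k":
            if k is None:
                raise ValueError("reduced models need k for the reference scale")
            T_ref = _small_branch_max(model_id, p, k, lam or p.lam)
        else:
            red = {"model4": "reduced4", "model10": "reduced10",
                   "model13": "reduced13"}.get(model_id)
            if red is None:
                raise ValueError("model1 needs an explicit T_ref")
            from .models import k_of_beta
            T_ref = _small_branch_max(red, p, k_of_beta(p), lam or p.lam)

    T = traj.T
    n = T.size
    i0 = int(cfg.transient_frac * n)
    if n - i0 < 16:
        raise ValueError("trajectory too short past the transient window")
    Tp = T[i0:]
    tp = traj.t[i0:]

    peak_T = float(T.max())
    escape_thr = max(cfg.escape_factor * T_ref, cfg.escape_floor)
    escaped = bool(peak_T > escape_thr) or traj.diverged

    # oscillation: amplitude relative to the running level, not collapsing
    amp = float(Tp.max() - Tp.min())
    level = max(float(np.mean(Tp)), 1e-12)
    q = (n - i0) // 2
    amp_a = float(Tp[:q].max() - Tp[:q].min()) if q > 2 else amp
    amp_b = float(Tp[q:].max() - Tp[q:].min()) if q > 2 else amp
    collapse = amp_b / max(amp_a, 1e-300)
    idx, _ = find_peaks(Tp)
    n_peaks = int(idx.size)
    period = float(np.mean(np.diff(tp[idx]))) if n_peaks >= 2 else math.nan

    significant = amp > cfg.osc_rtol * level
    sustained = bool(significant and collapse > cfg.decay_ratio and
                     (n_peaks >= cfg.min_peaks or amp > 0.5 * level))
    # a true limit cycle holds its amplitude (collapse ~ 1); a slowly
    # damped spiral shows intermediate collapse and needs a longer look
    ambiguous = bool(significant and not sustained) or (
        sustained and n_peaks < cfg.min_peaks) or (
        sustained and collapse < 0.97)

    return ResponseSummary(
        initiated=bool(escaped or sustained),
        escaped=escaped,
        sustained_oscillation=sustained,
        peak_T=peak_T,
        n_oscillation_peaks=n_peaks,
        T_max=float(Tp.max()),
        T_min=float(Tp.min()),
        period=period,
        T_ref=float(T_ref),
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _homeostatic_distance(traj: Trajectory, p: ParameterSet) -> float:
    target = homeostatic_state(traj.model_id, p)
    final = traj.y[:, -1]
    scale = np.maximum(np.abs(target), 1.0)
    return float(np.max(np.abs(final - target) / scale))


def scenario_ag_clearance(p: ParameterSet, beta_on: float, t_clear: float,
                          t_end: float | None = None,
                          model_id: str = "model13",
                          tol: float = 1e-3) -> tuple[Trajectory, dict]:
    """Stimulate, then clear the antigen: does the system return home?

    Runs the model with constant ``beta_on`` until ``t_clear``, then with
    beta = 0 until ``t_end``. The verdict records whether the final state
    is within ``tol`` (relative, component-wise) of the unstimulated
    homeostatic state. With Tregs present the response is suppressed and
    the system returns; the fratricide-only model stays on its saturated
    branch — hysteresis.
    """
    if t_end is None:
        t_end = t_clear + 4000.0
    sched = StimulationSchedule((
        (0.0, t_clear, beta_on), (t_clear, t_end, 0.0)))
    traj = integrate(model_id, p, schedule=sched, t_span=(0.0, t_end))
    dist = _homeostatic_distance(traj, p)
    verdict = {
        "returned_to_homeostasis": bool(dist <= tol),
        "final_distance": dist,
        "peak_T": float(traj.T.max()),
        "tol": tol,
    }
    return traj, verdict


def scenario_treg_depletion(p: ParameterSet, beta_chronic: float,
                            depletion_window: tuple[float, float],
                            t_end: float | None = None,
                            depleted_renewal_fraction: float = 0.0,
                            reset_nhat: bool = True,
                            config: ResponseConfig | None = None,
                            ) -> tuple[Trajectory, dict]:
    """Deplete resting Tregs during chronic over-suppressed stimulation.

    Under chronic stimulation (``beta_chronic`` above the over-suppression
    bound) the system sits at the small Treg-controlled equilibrium. During
    the window the resting-Treg renewal is scaled by
    ``depleted_renewal_fraction`` (default 0: full transient lam -> 0) and
    the resting-Treg pool is optionally cleared at the window start. The
    verdict asks whether a proliferation burst (the response-initiation
    escape test against the pre-window level) occurs during or after the
    window but not in the corresponding pre-window period.
    """
    cfg = config or ResponseConfig()
    t_dep0, t_dep1 = depletion_window
    if not 0 < t_dep0 < t_dep1:
        raise ValueError("depletion window must satisfy 0 < start < end")
    if t_end is None:
        t_end = t_dep1 + 2000.0

    # phase 1: chronic stimulation
    tr1 = integrate("model13", p, t_span=(0.0, t_dep0),
                    schedule=StimulationSchedule.constant(beta_chronic, t_dep0))
    y = tr1.y[:, -1].copy()
    if reset_nhat:
        y[1] = 0.0

    # phase 2: depletion window (suppressed resting-Treg renewal)
    frac = depleted_renewal_fraction

    def rhs_dep(t, yv):
        base = rhs_model13(yv, p, beta_chronic, allow_negative=True)
        # remove the withheld fraction of resting-Treg renewal
        base[1] -= (1.0 - frac) * p.lam * p.N0
        return base

    n2 = max(32, int(2 * (t_dep1 - t_dep0)) + 1)
    t2 = np.linspace(t_dep0, t_dep1, n2)
    from scipy.integrate import solve_ivp

    sol2 = solve_ivp(rhs_dep, (t_dep0, t_dep1), y, method="LSODA",
                     rtol=1e-8, atol=1e-10, t_eval=t2)

    # phase 3: renewal restored
    tr3 = integrate("model13", p, t_span=(t_dep1, t_end), init=np.maximum(sol2.y[:, -1], 0.0),
                    schedule=StimulationSchedule.constant(beta_chronic, t_end,
                                                          t_start=t_dep1))

    t = np.concatenate([tr1.t, sol2.t, tr3.t])
    yy = np.concatenate([tr1.y, sol2.y, tr3.y], axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    traj = Trajectory("model13", t[keep], yy[:, keep],
                      events=[(t_dep0, "depletion_start"),
                              (t_dep1, "depletion_end")])

    it = traj.names.index("T")
    pre = tr1.y[it]
    post_mask = t[keep] >= t_dep0
    post_peak = float(yy[it, keep][post_mask].max())
    # pre-window reference: the settled chronic level (last half of phase 1)
    pre_level = float(pre[len(pre) // 2:].max())
    thr = max(cfg.escape_factor * pre_level, cfg.escape_floor)
    verdict = {
        "chronic_level_T": pre_level,
        "peak_T_after_depletion": post_peak,
        "response_restored": bool(post_peak > thr),
        "escape_threshold": thr,
    }
    return traj, verdict
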