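"""Equilibria, stability, and closed-form thresholds of the nested models.

Equilibrium finding is exact where the algebra permits it: after
eliminating IL-2 (and activated Tregs) through their steady-state
relations, every model's equilibria are roots of a low-degree polynomial,
which is solved by companion-matrix root finding and polished by Newton
iteration. A deterministic multi-start root finder is provided as an
independent numerical oracle.

Branch naming follows the convention used throughout the analysis:
``T1`` the trivial/low branch, ``T2`` the unstable threshold branch,
``T3`` the fratricide-saturated branch, ``T4`` the Treg-controlled branch,
``T5`` the non-physical (negative-component) branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize
from scipy.stats import qmc

from .models import MODELS, get_model, k_of_beta
from .params import ParameterSet

__all__ = [
    "EquilibriumPoint", "ThresholdSet",
    "equilibria_model1_closed_form", "condition_positive_T2",
    "k_minus", "c_minus", "initiation_bounds",
    "find_equilibria", "jacobian_and_classify", "multistart_equilibria",
    "MARGINAL_TOL",
]

#: Eigenvalue real parts closer to zero than this are "marginal": at a
#: bifurcation point the leading eigenvalue sits exactly on the axis and a
#: stable/unstable call would be numerical noise.
MARGINAL_TOL = 1e-9

_DEDUP_RTOL = 1e-6


@dataclass(frozen=True)
class EquilibriumPoint:
    """A steady state with its linearization.

    ``stability`` is one of ``stable`` (all eigenvalue real parts < 0),
    ``unstable`` (all > 0), ``saddle`` (mixed), or ``marginal`` (a real
    part within :data:`MARGINAL_TOL` of zero).
    """

    model_id: str
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    residual: float
    label: str | None = None
    physical: bool = True
    note: str | None = None

    @property
    def T(self) -> float:
        idx = get_model(self.model_id).names.index("T")
        return float(self.state[idx])

    @property
    def n_unstable(self) -> int:
        return int(np.sum(self.eigenvalues.real > MARGINAL_TOL))

    def __repr__(self) -> str:  # compact: arrays are noisy
        comps = ", ".join(
            f"{n}={v:.6g}"
            for n, v in zip(get_model(self.model_id).names, self.state)
        )
        return (f"EquilibriumPoint({self.model_id}: {comps}; "
                f"{self.stability}, label={self.label})")


@dataclass(frozen=True)
class ThresholdSet:
    """Existence thresholds of the stimulated models.

    ``k_minus``: activation rate above which the influx-driven T/IL-2
    system (no fratricide) loses all equilibria and proliferates without
    bound. ``c_minus``: fratricide rate above which the saturated branch
    T3 disappears. ``beta_init``: the stimulation bound ``g*k-/(N0-k-)``;
    finite only when ``N0 > k_minus``.
    """

    k_minus: float
    c_minus: float
    beta_init: float
    beta_init_exists: bool
    g: float = field(default=np.nan)


def _classify(eigenvalues: np.ndarray) -> str:
    re = eigenvalues.real
    if np.any(np.abs(re) < MARGINAL_TOL):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def _point(model_id, state, p, drive, residual=None, label=None, note=None):
    info = get_model(model_id)
    state = np.asarray(state, dtype=float)
    if residual is None:
        residual = float(np.max(np.abs(
            info.rhs(state, p, drive, allow_negative=True))))
    eig = np.linalg.eigvals(info.jac(state, p, drive))
    return EquilibriumPoint(
        model_id=model_id,
        state=state,
        eigenvalues=eig,
        stability=_classify(eig),
        residual=residual,
        label=label,
        physical=bool(np.all(state >= -1e-9)),
        note=note,
    )


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def condition_positive_T2(p: ParameterSet) -> bool:
    """Quality condition on activated T cell clones: ``a*d - b*e > 0``.

    Proliferation times secretion must beat death times consumption for the
    nontrivial threshold state to sit at positive population size.
    """
    return p.a * p.d - p.b * p.e > 0


def equilibria_model1_closed_form(p: ParameterSet) -> list[EquilibriumPoint]:
    """The two steady states of the minimal T/IL-2 model.

    The origin (T1) and, when ``a*d != b*e``, the threshold state
    ``(T2, I2) = (b*f/(a*d - b*e), b/a)`` whose stable manifold separates
    decay from unlimited proliferation.
    """
    points = [_point("model1", (0.0, 0.0), p, 0.0, residual=0.0, label="T1")]
    denom = p.a * p.d - p.b * p.e
    if denom == 0:
        points[0] = _point("model1", (0.0, 0.0), p, 0.0, residual=0.0,
                           label="T1",
                           note="a*d == b*e: nontrivial equilibrium at infinity")
        return points
    T2 = p.b * p.f / denom
    I2 = p.b / p.a
    points.append(_point("model1", (T2, I2), p, 0.0, label="T2"))
    return points


def k_minus(p: ParameterSet) -> float:
    """Fold of the influx-driven T/IL-2 system (no fratricide).

    ``k- = (a*d*f/e**2) * (1 - sqrt(1 - b*e/(a*d)))**2``. For influx
    ``k > k-`` the system has no equilibria and the activated population
    grows without bound. The formula is the smaller root of the
    discriminant of ``(ad-be) T^2 + (ke-bf) T + kf`` in k and is
    cross-validated against numerical fold continuation in the test suite.
    """
    ad, be = p.a * p.d, p.b * p.e
    if be > ad:
        raise ValueError("k- requires a*d >= b*e (positive-threshold condition)")
    if p.e == 0:
        raise ValueError("k- is undefined for e == 0")
    return ad * p.f / p.e**2 * (1.0 - math.sqrt(1.0 - be / ad)) ** 2


def c_minus(p: ParameterSet) -> float:
    """Fratricide threshold ``c- = (sqrt(a*d) - sqrt(b*e))**2 / f``.

    The saturated branch T3 exists only for ``c < c-``; stronger
    activation-induced cell death removes any saturated immune response.
    """
    ad, be = p.a * p.d, p.b * p.e
    if be > ad:
        raise ValueError("c- requires a*d >= b*e (positive-threshold condition)")
    return (math.sqrt(ad) - math.sqrt(be)) ** 2 / p.f


def initiation_bounds(p: ParameterSet) -> ThresholdSet:
    """Stimulation bound for initiating unlimited proliferation.

    Initiation requires ``k > k-``; since ``k = beta*N0/(g+beta) < N0``,
    a finite initiating stimulation ``beta > g*k-/(N0-k-)`` exists only
    when the naive renewal rate exceeds the fold: ``N0 > k-``. Otherwise no
    stimulation, however strong, can initiate the response.
    """
    km = k_minus(p)
    cm = c_minus(p)
    if p.N0 > km:
        return ThresholdSet(km, cm, p.g * km / (p.N0 - km), True, g=p.g)
    return ThresholdSet(km, cm, math.inf, False, g=p.g)


# ---------------------------------------------------------------------------
# polynomial equilibrium finding
# ---------------------------------------------------------------------------

def _real_roots(coefs):
    """Real roots of a polynomial given lowest-order-first coefficients."""
    coefs = np.trim_zeros(np.asarray(coefs, dtype=float), "b")
    if coefs.size <= 1:
        return []
    roots = npoly.polyroots(coefs)
    return [float(r.real) for r in np.atleast_1d(roots) if abs(r.imag) < 1e-9]


def _i_of_t(p, T):
    return p.d * T / (p.e * T + p.f)


def _reduced4_states(p, k):
    # (ad-be) T^2 + (ke-bf) T + kf = 0, I from the IL-2 balance
    coefs = [k * p.f, k * p.e - p.b * p.f, p.a * p.d - p.b * p.e]
    states = [(T, _i_of_t(p, T)) for T in _real_roots(coefs)]
    if k == 0 and all(abs(s[0]) > 1e-12 for s in states):
        states.append((0.0, 0.0))
    return states


def _reduced10_states(p, k):
    # -ce T^3 + (ad - be - cf) T^2 + (ke - bf) T + kf = 0
    coefs = [k * p.f, k * p.e - p.b * p.f,
             p.a * p.d - p.b * p.e - p.c * p.f, -p.c * p.e]
    states = [(T, _i_of_t(p, T)) for T in _real_roots(coefs)]
    if k == 0 and all(abs(s[0]) > 1e-12 for s in states):
        states.append((0.0, 0.0))
    return states


def _reduced13_states(p, k, lam):
    """All real steady states of the reduced Tconv/Treg/IL-2 system.

    Eliminating R (Treg balance) and T (IL-2 balance) leaves a quintic in
    IL-2; spurious roots introduced by clearing the denominators
    ``A = b - eps*a*I`` and ``B = d - e*I`` are removed by a residual check
    after back-substitution. When ``lam*k == 0`` the Treg balance
    degenerates and the two factor branches (R = 0, and I pinned at
    ``b/(eps*a)``) are enumerated directly.
    """
    a, b, c, d, e, f = p.a, p.b, p.c, p.d, p.e, p.f
    gam, eps = p.gamma, p.epsilon
    states: list[tuple[float, float, float]] = []

    if lam * k == 0.0:
        # branch R = 0: the reduced model-10 subsystem
        for T, I in _reduced10_states(p, k):
            states.append((T, 0.0, I))
        # branch I = b/(eps a): R from IL-2 balance, T from the T balance
        if eps * a > 0:
            I0 = b / (eps * a)
            if abs(d - e * I0) > 1e-300:
                # R = T (d - e I0)/(e I0) - f/e; T balance is linear/quadratic
                # a I0 T - b T - c T^2 - gam R T + k = 0
                r1 = (d - e * I0) / (e * I0)
                r0 = -f / e
                coefs = [k, a * I0 - b - gam * r0, -(c + gam * r1)]
                for T in _real_roots(coefs):
                    states.append((T, r1 * T + r0, I0))
    else:
        I = np.array([0.0, 1.0])
        A = np.array([b, -eps * a])
        B = np.array([d, -e])
        C = np.array([e * lam * k + f * b, -f * eps * a])  # e*lam*k + f*A
        pm = npoly.polymul
        terms = [
            pm(pm(pm(I, C), pm(A, B)), np.array([-b, a])),
            -c * pm(pm(I, I), pm(C, C)),
            -gam * lam * k * pm(pm(I, C), B),
            k * pm(pm(A, A), pm(B, B)),
        ]
        coefs = np.zeros(6)
        for t in terms:
            coefs[: len(t)] += t
        for Iv in _real_roots(coefs):
            Av, Bv = b - eps * a * Iv, d - e * Iv
            if abs(Av) < 1e-300 or abs(Bv) < 1e-300:
                continue
            R = lam * k / Av
            T = Iv * (e * R + f) / Bv
            states.append((T, R, Iv))
    return states


def _polish_and_collect(model_id, states, p, drive, lam=None, tol=1e-9):
    """Newton-polish candidate states, drop spurious ones, dedup, label."""
    info = get_model(model_id)
    pp = p if lam is None else p.replace(lam=lam)

    def fun(y):
        return info.rhs(y, pp, drive, allow_negative=True)

    def jac(y):
        return info.jac(y, pp, drive)

    points = []
    for s in states:
        y = np.asarray(s, dtype=float)
        scale = 1.0 + float(np.max(np.abs(y)))
        sol = optimize.root(fun, y, jac=jac, method="hybr",
                            options={"xtol": 1e-14})
        # accept the polish only if it stays on the same root; a large move
        # means the candidate was spurious (a denominator root of the
        # elimination) and Newton slid elsewhere
        if np.max(np.abs(sol.x - y)) <= 1e-3 * scale and (
                np.max(np.abs(fun(sol.x))) <= np.max(np.abs(fun(y)))):
            y = sol.x
        res = float(np.max(np.abs(fun(y))))
        if res > tol * scale:
            continue
        points.append(y)

    points = _dedup(points)
    points.sort(key=lambda y: y[info.names.index("T")])
    eq = [_point(model_id, y, pp, drive) for y in points]
    return _label_points(model_id, eq)


def _dedup(states):
    out = []
    for y in states:
        for z in out:
            denom = 1.0 + max(np.max(np.abs(y)), np.max(np.abs(z)))
            if np.max(np.abs(y - z)) < _DEDUP_RTOL * denom:
                break
        else:
            out.append(y)
    return out


def _label_points(model_id, points):
    """Assign branch names by position along the T axis.

    Branches with negative T are T5 (the non-physical branch tracked but
    never plotted). Among T >= 0, in increasing T: the largest is the
    saturated branch T3, the second largest in the Treg model is the
    Treg-controlled branch T4, and the remaining low/threshold pair are
    T1/T2. Note the saturated branch keeps the T3 name even when its Treg
    component is slightly negative (which it is for any lam*k > 0); the
    ``physical`` flag records that honestly.
    """
    if not points:
        return points
    top = max(points, key=lambda q: q.T)
    t5 = [q for q in points if not q.physical and q is not top]
    main = [q for q in points if q is top or q.physical]
    labels = {id(q): "T5" for q in t5}
    if model_id in ("reduced13", "model13"):
        scheme = {1: ["T4"], 2: ["T4", "T3"], 3: ["T1", "T4", "T3"],
                  4: ["T1", "T2", "T4", "T3"]}
    else:
        scheme = {1: ["T1"], 2: ["T1", "T2"], 3: ["T1", "T2", "T3"]}
    names = scheme.get(len(main), [None] * len(main))
    if model_id in ("reduced10", "model10") and len(main) == 1 and (
            main[0].stability == "stable" and main[0].T > 100.0):
        # above the low-branch fold only the fratricide-saturated branch
        # survives; keep its name
        names = ["T3"]
    for q, name in zip(main, names):
        labels[id(q)] = name
    out = []
    for q in points:
        out.append(EquilibriumPoint(
            model_id=q.model_id, state=q.state, eigenvalues=q.eigenvalues,
            stability=q.stability, residual=q.residual,
            label=labels.get(id(q)), physical=q.physical, note=q.note))
    return out


def find_equilibria(model_id: str, p: ParameterSet, k: float | None = None,
                    lam: float | None = None) -> list[EquilibriumPoint]:
    """All real equilibria of a model, with stability and branch labels.

    Reduced models require the activation rate ``k`` (and use ``lam`` from
    ``p`` unless given). Full models use ``p.beta``; their naive
    compartments sit at ``N0/(g+beta)`` (scaled by lam for resting Tregs)
    and the remaining components coincide with the reduced equilibria at
    ``k = k_of_beta(p)``. Non-physical equilibria (negative components) are
    retained and flagged, matching how the unstable negative branch T5 is
    tracked in the bifurcation diagrams.
    """
    lam = p.lam if lam is None else lam
    if model_id == "model1":
        pts = equilibria_model1_closed_form(p)
        return pts
    if model_id in ("reduced4", "reduced10", "reduced13"):
        if k is None:
            raise ValueError(f"{model_id} requires the activation rate k")
        if model_id == "reduced4":
            states = _reduced4_states(p, k)
        elif model_id == "reduced10":
            states = _reduced10_states(p, k)
        else:
            states = _reduced13_states(p, k, lam)
        return _polish_and_collect(model_id, states, p, k, lam=lam)
    if model_id in ("model4", "model10", "model13"):
        if k is not None:
            raise ValueError(
                f"{model_id} is driven by beta from the parameter set; "
                "pass k to the reduced models instead")
        beta = p.beta
        Nst = p.N0 / (p.g + beta) if (p.g + beta) > 0 else math.inf
        if not math.isfinite(Nst):
            raise ValueError("equilibria undefined for g + beta == 0")
        keff = beta * Nst
        red = {"model4": "reduced4", "model10": "reduced10",
               "model13": "reduced13"}[model_id]
        sub = find_equilibria(red, p, k=keff, lam=lam)
        out = []
        for q in sub:
            if model_id == "model13":
                state = np.concatenate(([Nst, lam * Nst], q.state))
            else:
                state = np.concatenate(([Nst], q.state))
            out.append(_point(model_id, state, p, beta, label=q.label))
        return out
    raise ValueError(f"unknown model {model_id!r}")


# ---------------------------------------------------------------------------
# stability classification and the numeric oracle
# ---------------------------------------------------------------------------

def jacobian_and_classify(model_id: str, state, p: ParameterSet,
                          k: float | None = None, lam: float | None = None,
                          residual_tol: float = 1e-6) -> EquilibriumPoint:
    """Linearize at a steady state and classify it.

    The Jacobian is the analytic one derived from the model equations, not
    a finite difference. Inputs that are not equilibria (residual above
    ``residual_tol`` relative to the state scale) are rejected.
    """
    info = get_model(model_id)
    lam = p.lam if lam is None else lam
    pp = p.replace(lam=lam)
    if info.drive == "k":
        if k is None:
            raise ValueError(f"{model_id} requires k")
        drive = k
    else:
        drive = p.beta
    state = np.asarray(state, dtype=float)
    res = float(np.max(np.abs(info.rhs(state, pp, drive, allow_negative=True))))
    scale = 1.0 + float(np.max(np.abs(state)))
    if res > residual_tol * scale:
        raise ValueError(
            f"state is not an equilibrium: residual {res:.3g} exceeds "
            f"{residual_tol:.1g} * scale {scale:.3g}")
    return _point(model_id, state, pp, drive, residual=res)


def multistart_equilibria(model_id: str, p: ParameterSet,
                          k: float | None = None, lam: float | None = None,
                          n_starts: int = 64, seed: int = 0,
                          caps: tuple[float, ...] | None = None,
                          tol: float = 1e-12) -> list[EquilibriumPoint]:
    """Find equilibria by deterministic multi-start Newton iteration.

    Starts are a seeded Sobol' design over ``[0, cap]^dim`` (per-component
    caps default to generous multiples of the saturated-branch scale).
    Serves as the independent numerical cross-check of the closed-form and
    polynomial routes.
    """
    info = get_model(model_id)
    lam = p.lam if lam is None else lam
    pp = p.replace(lam=lam)
    if info.drive == "k":
        if k is None:
            raise ValueError(f"{model_id} requires k")
        drive = k
    else:
        drive = p.beta

    if caps is None:
        t_cap = 3.0 * max(
            abs(p.b * p.f / (p.a * p.d - p.b * p.e))
            if p.a * p.d != p.b * p.e else 1.0,
            (p.a * p.d - p.b * p.e) / (p.c * p.e) if p.c > 0 and p.e > 0 else 0.0,
            1.0,
        )
        i_cap = 3.0 * max(p.d / p.e if p.e > 0 else 1.0, p.b / p.a if p.a > 0 else 1.0)
        per = {"T": t_cap, "I": i_cap, "R": max(200.0, 3 * p.d / max(p.e, 1e-12)),
               "N": 3.0 * p.N0 / max(p.g, 1e-12),
               "Nhat": 3.0 * max(p.lam, 1e-3) * p.N0 / max(p.g, 1e-12)}
        caps = tuple(per[n] for n in info.names)

    sampler = qmc.Sobol(d=info.dim, scramble=True, seed=seed)
    n_pow2 = 1 << max(1, (n_starts - 1).bit_length())
    u = sampler.random(n_pow2)[:n_starts]
    # half the design linear in the caps, half cubed (biased towards the
    # origin, where the low-population roots live), plus the zero start
    half = n_starts // 2
    starts = np.vstack([
        u[:half] * np.asarray(caps),
        u[half:] ** 3 * np.asarray(caps),
        np.zeros((1, info.dim)),
    ])

    def fun(y):
        return info.rhs(y, pp, drive, allow_negative=True)

    def jac(y):
        return info.jac(y, pp, drive)

    found = []
    for y0 in starts:
        sol = optimize.root(fun, y0, jac=jac, method="hybr",
                            options={"xtol": 1e-14})
        if not sol.success:
            continue
        scale = 1.0 + float(np.max(np.abs(sol.x)))
        if float(np.max(np.abs(fun(sol.x)))) <= tol * scale:
            found.append(sol.x)
    found = _dedup(found)
    found.sort(key=lambda y: y[info.names.index("T")])
    return _label_points(model_id, [_point(model_id, y, pp, drive) for y in found])
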