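"""One-parameter continuation of equilibrium branches.

A pseudo-arclength predictor–corrector tracks equilibrium curves of the
reduced models through turning points. The continuation parameter can be
the T cell activation rate ``k``, the fratricide rate ``c``, or the
relative Treg renewal ``lam``. Folds are detected by a sign change of
``det J`` along the branch and refined by solving the augmented fold
system; Hopf points by a sign change of the leading complex-pair real part,
refined by bisection in the parameter with Newton-corrected states.

States and parameter are continued in scaled variables so that branches
spanning several orders of magnitude in population size (the saturated
branch sits near 3e4 cells) step reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy import optimize

from .equilibria import EquilibriumPoint, MARGINAL_TOL, _point, find_equilibria
from .models import get_model
from .params import ParameterSet

__all__ = ["BifurcationBranch", "SpecialPoint", "continue_branch"]

_COMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class SpecialPoint:
    """A fold (zero real eigenvalue) or Hopf (imaginary pair) point."""

    type: str  # "fold" | "hopf"
    parameter_name: str
    parameter_value: float
    state: np.ndarray

    def __repr__(self) -> str:
        return (f"SpecialPoint({self.type} at {self.parameter_name}="
                f"{self.parameter_value:.6g})")


@dataclass
class BifurcationBranch:
    """An equilibrium curve: ordered ``(parameter, EquilibriumPoint)``."""

    model_id: str
    parameter_name: str
    samples: list[tuple[float, EquilibriumPoint]] = field(default_factory=list)
    truncated: bool = False  # branch left the state cap

    @property
    def parameter_values(self) -> np.ndarray:
        return np.array([a for a, _ in self.samples])

    @property
    def T_values(self) -> np.ndarray:
        return np.array([q.T for _, q in self.samples])

    @property
    def stabilities(self) -> list[str]:
        return [q.stability for _, q in self.samples]


class _Problem:
    """G(x, alpha) = 0 with analytic Jacobians in x and alpha."""

    def __init__(self, model_id: str, p: ParameterSet, parameter_name: str,
                 k: float, lam: float):
        info = get_model(model_id)
        if info.drive != "k":
            raise ValueError(
                "continuation operates on the reduced (activation-driven) "
                f"models, got {model_id!r}")
        self.info = info
        self.p = p.replace(lam=lam)
        self.parameter_name = parameter_name
        self.k = k
        self.lam = lam
        if parameter_name not in ("k", "c", "lam"):
            raise ValueError(f"unsupported parameter {parameter_name!r}")
        if parameter_name == "lam" and model_id != "reduced13":
            raise ValueError("lam only parametrizes reduced13")

    def _pk(self, alpha):
        # continuation probes may step marginally outside the physical
        # parameter domain (e.g. c -> 0-); bypass ParameterSet validation
        # for those evaluations only
        if self.parameter_name == "k":
            return self.p, alpha
        if self.parameter_name == "c":
            return SimpleNamespace(**{**self.p.to_dict(), "c": alpha}), self.k
        return SimpleNamespace(**{**self.p.to_dict(), "lam": alpha}), self.k

    def G(self, x, alpha):
        p, k = self._pk(alpha)
        return self.info.rhs(x, p, k, allow_negative=True)

    def Jx(self, x, alpha):
        p, k = self._pk(alpha)
        return self.info.jac(x, p, k)

    def Ga(self, x, alpha):
        n = self.info.dim
        out = np.zeros(n)
        it = self.info.names.index("T")
        if self.parameter_name == "k":
            out[it] = 1.0
            if self.info.model_id == "reduced13":
                out[self.info.names.index("R")] = self._pk(alpha)[0].lam
        elif self.parameter_name == "c":
            out[it] = -x[it] ** 2
        else:  # lam
            out[self.info.names.index("R")] = self.k
        return out

    def equilibria(self, alpha):
        if self.parameter_name == "k":
            p, k = self.p, alpha
        elif self.parameter_name == "c":
            p, k = self.p.replace(c=max(alpha, 0.0)), self.k
        else:
            p, k = self.p.replace(lam=max(alpha, 0.0)), self.k
        return find_equilibria(self.info.model_id, p, k=k)


def _tangent(prob, x, alpha, w, aw, prev=None):
    """Unit tangent of the scaled solution curve via SVD nullspace."""
    n = len(x)
    M = np.empty((n, n + 1))
    M[:, :n] = prob.Jx(x, alpha) * w[None, :]
    M[:, n] = prob.Ga(x, alpha) * aw
    _, _, vt = np.linalg.svd(M)
    t = vt[-1]
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _correct(prob, z_pred, t, w, aw, tol=1e-11, maxit=12):
    """Newton-correct onto the branch, orthogonal to the tangent."""
    n = len(z_pred) - 1
    z = z_pred.copy()
    for _ in range(maxit):
        x, alpha = z[:n] * w, z[n] * aw
        g = prob.G(x, alpha)
        r = np.concatenate([g, [np.dot(t, z - z_pred)]])
        scale = 1.0 + np.max(np.abs(g))
        M = np.empty((n + 1, n + 1))
        M[:n, :n] = prob.Jx(x, alpha) * w[None, :]
        M[:n, n] = prob.Ga(x, alpha) * aw
        M[n, :] = t
        try:
            dz = np.linalg.solve(M, r)
        except np.linalg.LinAlgError:
            return None
        z = z - dz
        if np.max(np.abs(dz)) < tol and np.max(np.abs(g)) < 1e-8 * scale:
            return z
    return None


def _complex_lead(eig):
    """Largest real part among complex-pair eigenvalues, or nan."""
    cm = eig[np.abs(eig.imag) > _COMPLEX_TOL]
    return float(np.max(cm.real)) if cm.size else np.nan


def _refine_fold(prob, x0, alpha0):
    n = len(x0)
    scale = np.maximum(np.abs(x0), 1.0)

    def fun(z):
        x, alpha = z[:n] * scale, z[n]
        detj = np.linalg.det(prob.Jx(x, alpha))
        return np.concatenate([prob.G(x, alpha), [detj]])

    sol = optimize.root(fun, np.concatenate([x0 / scale, [alpha0]]),
                        method="hybr", options={"xtol": 1e-13})
    if sol.success or np.max(np.abs(fun(sol.x))) < 1e-8:
        return sol.x[:n] * scale, float(sol.x[n])
    return x0, alpha0


def _refine_hopf(prob, xa, aa, xb, ab):
    """Bisect the complex-pair real part in alpha between two samples."""

    def solve_at(alpha, x_guess):
        sol = optimize.root(lambda x: prob.G(x, alpha), x_guess,
                            jac=lambda x: prob.Jx(x, alpha),
                            method="hybr", options={"xtol": 1e-13})
        return sol.x

    def test(alpha, x_guess):
        x = solve_at(alpha, x_guess)
        return _complex_lead(np.linalg.eigvals(prob.Jx(x, alpha))), x

    fa, xa = test(aa, xa)
    fb, xb = test(ab, xb)
    if not (np.isfinite(fa) and np.isfinite(fb)) or fa * fb > 0:
        return None
    for _ in range(60):
        am = 0.5 * (aa + ab)
        fm, xm = test(am, 0.5 * (xa + xb))
        if not np.isfinite(fm):
            return None
        if fa * fm <= 0:
            ab, xb, fb = am, xm, fm
        else:
            aa, xa, fa = am, xm, fm
        if abs(ab - aa) < 1e-12 * max(1.0, abs(ab)):
            break
    return 0.5 * (xa + xb), 0.5 * (aa + ab)


def _continue_from(prob, x0, alpha0, prange, direction, state_cap,
                   h0=1e-2, hmax=0.15, hmin=1e-7, max_steps=6000):
    """Trace one direction of a branch; returns (samples, specials, truncated).

    Samples are (alpha, x, eigenvalues) triples in unscaled units.
    """
    n = len(x0)
    aw = max(prange[1] - prange[0], 1e-6)

    # seed correction at fixed alpha
    sol = optimize.root(lambda x: prob.G(x, alpha0), x0,
                        jac=lambda x: prob.Jx(x, alpha0),
                        method="hybr", options={"xtol": 1e-13})
    x0 = sol.x
    if np.max(np.abs(prob.G(x0, alpha0))) > 1e-7 * (1 + np.max(np.abs(x0))):
        return [], [], False

    # state scaling follows the branch so that curves spanning several
    # orders of magnitude keep making progress
    w = np.maximum(np.abs(x0), 1.0)
    z = np.concatenate([x0 / w, [alpha0 / aw]])
    t = _tangent(prob, x0, alpha0, w, aw)
    if np.sign(t[n]) != direction and t[n] != 0:
        t = -t

    eig = np.linalg.eigvals(prob.Jx(x0, alpha0))
    samples = [(alpha0, x0.copy(), eig)]
    specials: list[SpecialPoint] = []
    truncated = False
    h = h0

    for _ in range(max_steps):
        z_new = None
        while h >= hmin:
            z_pred = z + h * t
            z_new = _correct(prob, z_pred, t, w, aw)
            if z_new is not None:
                break
            h *= 0.5
        if z_new is None:
            break
        x_new, a_new = z_new[:n] * w, z_new[n] * aw
        eig_new = np.linalg.eigvals(prob.Jx(x_new, a_new))

        a_prev, x_prev, eig_prev = samples[-1]
        # fold: det J changes sign
        det_prev = np.prod(eig_prev).real
        det_new = np.prod(eig_new).real
        if det_prev * det_new < 0:
            xf, af = _refine_fold(prob, 0.5 * (x_prev + x_new),
                                  0.5 * (a_prev + a_new))
            if prange[0] - 1e-9 <= af <= prange[1] + 1e-9:
                specials.append(SpecialPoint("fold", prob.parameter_name,
                                             af, xf))
        # hopf: complex-pair real part changes sign
        c_prev, c_new = _complex_lead(eig_prev), _complex_lead(eig_new)
        if np.isfinite(c_prev) and np.isfinite(c_new) and c_prev * c_new < 0:
            ref = _refine_hopf(prob, x_prev, a_prev, x_new, a_new)
            if ref is not None and prange[0] - 1e-9 <= ref[1] <= prange[1] + 1e-9:
                specials.append(SpecialPoint("hopf", prob.parameter_name,
                                             ref[1], ref[0]))

        if np.max(np.abs(x_new)) > state_cap:
            truncated = True
            break
        samples.append((a_new, x_new, eig_new))
        # refresh scaling and re-express the tangent in the new units
        w_new = np.maximum(np.abs(x_new), 1.0)
        t_prev = np.concatenate([t[:n] * w / w_new, [t[n]]])
        t_prev /= np.linalg.norm(t_prev)
        w = w_new
        t = _tangent(prob, x_new, a_new, w, aw, prev=t_prev)
        z = np.concatenate([x_new / w, [a_new / aw]])
        h = min(h * 1.3, hmax)

        if not (prange[0] - 1e-9 <= a_new <= prange[1] + 1e-9):
            break
    return samples, specials, truncated


def _scaled_polyline(samples, a_scale):
    A = np.array([s[0] for s in samples])
    X = np.array([np.log1p(np.abs(s[1])) * np.sign(s[1]) for s in samples])
    return np.column_stack([A / a_scale, X])


def _scaled_point(alpha0, x0, a_scale):
    return np.concatenate([[alpha0 / a_scale],
                           np.log1p(np.abs(x0)) * np.sign(x0)])


def _covers_point(samples, alpha0, x0, a_scale, tol=0.05):
    """Does the branch polyline pass near (alpha0, x0)?

    Distances are measured in signed-log state coordinates so the test is
    meaningful across branches spanning several orders of magnitude, and
    against segments so folded curves (not functions of the parameter)
    are handled.
    """
    S = _scaled_polyline(samples, a_scale)
    P = _scaled_point(alpha0, x0, a_scale)
    if len(S) == 1:
        return bool(np.linalg.norm(P - S[0]) < tol)
    d = S[1:] - S[:-1]
    wvec = P[None, :] - S[:-1]
    denom = np.maximum((d * d).sum(axis=1), 1e-300)
    tt = np.clip((wvec * d).sum(axis=1) / denom, 0.0, 1.0)
    proj = S[:-1] + tt[:, None] * d
    return bool(np.min(np.linalg.norm(P - proj, axis=1)) < tol)


def _is_duplicate_branch(samples, kept_samples, a_scale):
    """A branch is a duplicate if nearly all of its probe points lie on an
    already-kept branch."""
    n = len(samples)
    idx = np.unique(np.linspace(0, n - 1, min(25, n)).astype(int))
    hits = sum(_covers_point(kept_samples, samples[i][0], samples[i][1],
                             a_scale) for i in idx)
    return hits >= 0.9 * len(idx)


def continue_branch(model_id: str, p: ParameterSet, parameter_name: str,
                    prange: tuple[float, float], lam: float | None = None,
                    k: float = 0.0, n_seeds: int = 7,
                    state_cap: float = 1e6,
                    ) -> tuple[list[BifurcationBranch], list[SpecialPoint]]:
    """Continue all equilibrium branches of a reduced model over a range.

    Parameters
    ----------
    model_id : {"reduced4", "reduced10", "reduced13"}
        Reduced (activation-driven) model.
    parameter_name : {"k", "c", "lam"}
        Continuation parameter. For "c" and "lam" the activation rate is
        held at ``k`` (default 0, the unstimulated diagrams).
    prange : (lo, hi)
        Parameter interval to cover.
    lam : float, optional
        Treg/naive renewal ratio; defaults to ``p.lam``.

    Returns branches (each sample carries the full equilibrium point with
    eigenvalues and stability) and the deduplicated fold/Hopf points.
    Branches escaping ``state_cap`` are truncated and flagged.
    """
    lam = p.lam if lam is None else lam
    lo, hi = map(float, prange)
    if not hi > lo:
        raise ValueError("prange must be increasing")
    prob = _Problem(model_id, p, parameter_name, k, lam)
    info = prob.info

    seeds = []
    for alpha in np.linspace(lo, hi, n_seeds):
        if parameter_name in ("c", "lam") and alpha < 0:
            continue
        for q in prob.equilibria(alpha):
            if np.max(np.abs(q.state)) <= state_cap:
                seeds.append((alpha, q.state))

    raw_branches: list[tuple[list, bool]] = []  # (samples, truncated)
    all_specials = []
    a_scale = hi - lo
    for alpha0, x0 in seeds:
        if any(_covers_point(smp, alpha0, x0, a_scale)
               for smp, _tr in raw_branches):
            continue
        fw, sp_f, tr_f = _continue_from(prob, x0, alpha0, (lo, hi), +1,
                                        state_cap)
        bw, sp_b, tr_b = _continue_from(prob, x0, alpha0, (lo, hi), -1,
                                        state_cap)
        if not fw and not bw:
            continue
        merged = list(reversed(bw)) + fw[1:]
        raw_branches.append((merged, tr_f or tr_b))
        all_specials.extend(sp_f + sp_b)

    # deduplicate branches traced more than once from different seeds
    kept: list[tuple[list, bool]] = []
    for smp, tr in raw_branches:
        if any(_is_duplicate_branch(smp, ksmp, a_scale) for ksmp, _ in kept):
            continue
        kept.append((smp, tr))

    branches = []
    for smp, tr in kept:
        br = BifurcationBranch(model_id=info.model_id,
                               parameter_name=parameter_name, truncated=tr)
        for alpha, x, _eig in smp:
            if not (lo - 1e-9 <= alpha <= hi + 1e-9):
                continue
            pp, kk = prob._pk(alpha)
            br.samples.append((float(alpha), _point(info.model_id, x, pp, kk)))
        if br.samples:
            branches.append(br)

    # deduplicate special points
    specials = []
    for sp in all_specials:
        if not any(sp.type == q.type and
                   abs(sp.parameter_value - q.parameter_value) <
                   1e-6 * (1 + abs(q.parameter_value))
                   for q in specials):
            specials.append(sp)
    specials.sort(key=lambda s: s.parameter_value)
    return branches, specials
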