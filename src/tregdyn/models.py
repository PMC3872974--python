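"""Right-hand sides and Jacobians of the nested activation models.

Four nested models of increasing biological detail share one parameter set:

``model1``   (T, I)            IL-2-driven proliferation of activated T cells.
``model4``   (N, T, I)         adds the naive compartment and stimulation beta.
``model10``  (N, T, I)         adds fratricide (-c T^2).
``model13``  (N, Nhat, T, R, I) adds resting/activated Tregs and IL-2
                               competition.

For bifurcation work each stimulated model also has a reduced form in which
the naive compartments are replaced by their steady-state influx: a constant
T cell activation rate ``k = beta*N0/(g+beta)`` (and ``khat = lam*k`` into
activated Tregs). These are ``reduced4``, ``reduced10`` and ``reduced13``.

State layout is plain ``numpy`` arrays in the component order listed above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ParameterSet

__all__ = [
    "rhs_model1", "rhs_model4", "rhs_model10", "rhs_model13",
    "rhs_reduced4", "rhs_reduced10", "rhs_reduced13",
    "jac_model1", "jac_model4", "jac_model10", "jac_model13",
    "jac_reduced4", "jac_reduced10", "jac_reduced13",
    "k_of_beta", "beta_of_k", "khat_of_k",
    "ModelInfo", "MODELS", "get_model",
]


def _check_state(state, n, allow_negative):
    y = np.asarray(state, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"expected state of length {n}, got shape {y.shape}")
    if not allow_negative and np.any(y < 0):
        raise ValueError(
            "negative state components are not physical; pass "
            "allow_negative=True for root-finding probes"
        )
    return y


# ---------------------------------------------------------------------------
# full models (driven by beta)
# ---------------------------------------------------------------------------

def rhs_model1(state, p: ParameterSet, *, allow_negative: bool = False):
    """(dT/dt, dI/dt) = (aIT - bT, dT - eIT - fI)."""
    T, I = _check_state(state, 2, allow_negative)
    return np.array([
        p.a * I * T - p.b * T,
        p.d * T - p.e * I * T - p.f * I,
    ])


def jac_model1(state, p: ParameterSet):
    T, I = np.asarray(state, dtype=float)
    return np.array([
        [p.a * I - p.b, p.a * T],
        [p.d - p.e * I, -p.e * T - p.f],
    ])


def rhs_model4(state, p: ParameterSet, beta: float | None = None, *,
               allow_negative: bool = False):
    """Naive compartment with renewal N0 feeding activation beta*N."""
    N, T, I = _check_state(state, 3, allow_negative)
    beta = p.beta if beta is None else beta
    return np.array([
        p.N0 - p.g * N - beta * N,
        p.a * I * T - p.b * T + beta * N,
        p.d * T - p.e * I * T - p.f * I,
    ])


def jac_model4(state, p: ParameterSet, beta: float | None = None):
    N, T, I = np.asarray(state, dtype=float)
    beta = p.beta if beta is None else beta
    return np.array([
        [-p.g - beta, 0.0, 0.0],
        [beta, p.a * I - p.b, p.a * T],
        [0.0, p.d - p.e * I, -p.e * T - p.f],
    ])


def rhs_model10(state, p: ParameterSet, beta: float | None = None, *,
                allow_negative: bool = False):
    """As ``model4`` with the fratricide loss -c T^2."""
    N, T, I = _check_state(state, 3, allow_negative)
    beta = p.beta if beta is None else beta
    return np.array([
        p.N0 - p.g * N - beta * N,
        p.a * I * T - p.b * T - p.c * T * T + beta * N,
        p.d * T - p.e * I * T - p.f * I,
    ])


def jac_model10(state, p: ParameterSet, beta: float | None = None):
    N, T, I = np.asarray(state, dtype=float)
    beta = p.beta if beta is None else beta
    return np.array([
        [-p.g - beta, 0.0, 0.0],
        [beta, p.a * I - p.b - 2.0 * p.c * T, p.a * T],
        [0.0, p.d - p.e * I, -p.e * T - p.f],
    ])


def rhs_model13(state, p: ParameterSet, beta: float | None = None, *,
                allow_negative: bool = False):
    """Full Tconv/Treg/IL-2 model.

    Resting Tregs (Nhat) renew at lam*N0 and activate at rate beta like
    naive T cells; activated Tregs (R) proliferate on IL-2 at relative rate
    epsilon, suppress activated T cells at rate gamma, and consume IL-2
    without secreting it.
    """
    N, Nh, T, R, I = _check_state(state, 5, allow_negative)
    beta = p.beta if beta is None else beta
    return np.array([
        p.N0 - p.g * N - beta * N,
        p.lam * p.N0 - p.g * Nh - beta * Nh,
        p.a * I * T - p.b * T - p.c * T * T - p.gamma * R * T + beta * N,
        p.epsilon * p.a * I * R - p.b * R + beta * Nh,
        p.d * T - p.e * I * (T + R) - p.f * I,
    ])


def jac_model13(state, p: ParameterSet, beta: float | None = None):
    N, Nh, T, R, I = np.asarray(state, dtype=float)
    beta = p.beta if beta is None else beta
    return np.array([
        [-p.g - beta, 0.0, 0.0, 0.0, 0.0],
        [0.0, -p.g - beta, 0.0, 0.0, 0.0],
        [beta, 0.0,
         p.a * I - p.b - 2.0 * p.c * T - p.gamma * R,
         -p.gamma * T, p.a * T],
        [0.0, beta, 0.0, p.epsilon * p.a * I - p.b, p.epsilon * p.a * R],
        [0.0, 0.0, p.d - p.e * I, -p.e * I, -p.e * (T + R) - p.f],
    ])


# ---------------------------------------------------------------------------
# reduced models (driven by a constant activation rate k)
# ---------------------------------------------------------------------------

def rhs_reduced4(state, p: ParameterSet, k: float, *,
                 allow_negative: bool = False):
    """``model4`` with the naive compartment at steady state: influx k."""
    if k < 0 and not allow_negative:
        raise ValueError("k must be >= 0")
    T, I = _check_state(state, 2, allow_negative)
    return np.array([
        p.a * I * T - p.b * T + k,
        p.d * T - p.e * I * T - p.f * I,
    ])


def jac_reduced4(state, p: ParameterSet, k: float = 0.0):
    return jac_model1(state, p)


def rhs_reduced10(state, p: ParameterSet, k: float, *,
                  allow_negative: bool = False):
    if k < 0 and not allow_negative:
        raise ValueError("k must be >= 0")
    T, I = _check_state(state, 2, allow_negative)
    return np.array([
        p.a * I * T - p.b * T - p.c * T * T + k,
        p.d * T - p.e * I * T - p.f * I,
    ])


def jac_reduced10(state, p: ParameterSet, k: float = 0.0):
    T, I = np.asarray(state, dtype=float)
    return np.array([
        [p.a * I - p.b - 2.0 * p.c * T, p.a * T],
        [p.d - p.e * I, -p.e * T - p.f],
    ])


def rhs_reduced13(state, p: ParameterSet, k: float, lam: float | None = None, *,
                  allow_negative: bool = False):
    """``model13`` with both resting compartments at steady state.

    Constant influx ``k`` feeds activated T cells and ``khat = lam*k`` feeds
    activated Tregs. This three-dimensional system carries the entire
    bifurcation structure of the full model.
    """
    if k < 0 and not allow_negative:
        raise ValueError("k must be >= 0")
    lam = p.lam if lam is None else lam
    T, R, I = _check_state(state, 3, allow_negative)
    return np.array([
        p.a * I * T - p.b * T - p.c * T * T - p.gamma * R * T + k,
        p.epsilon * p.a * I * R - p.b * R + lam * k,
        p.d * T - p.e * I * (T + R) - p.f * I,
    ])


def jac_reduced13(state, p: ParameterSet, k: float = 0.0,
                  lam: float | None = None):
    T, R, I = np.asarray(state, dtype=float)
    return np.array([
        [p.a * I - p.b - 2.0 * p.c * T - p.gamma * R, -p.gamma * T, p.a * T],
        [0.0, p.epsilon * p.a * I - p.b, p.epsilon * p.a * R],
        [p.d - p.e * I, -p.e * I, -p.e * (T + R) - p.f],
    ])


# ---------------------------------------------------------------------------
# activation-rate identities
# ---------------------------------------------------------------------------

def k_of_beta(p: ParameterSet, beta: float | None = None) -> float:
    """Steady-state T cell activation ``k = beta*N0/(g+beta)``.

    Monotonically increasing in beta and bounded above by N0: no
    stimulation can activate T cells faster than the naive compartment
    renews.
    """
    beta = p.beta if beta is None else beta
    if p.g + beta <= 0:
        raise ValueError("k is undefined for g + beta == 0")
    return beta * p.N0 / (p.g + beta)


def beta_of_k(p: ParameterSet, k: float) -> float:
    """Invert :func:`k_of_beta`; only defined for ``k < N0``."""
    if not 0 <= k < p.N0:
        raise ValueError(f"no finite beta reaches k={k} (requires 0 <= k < N0)")
    return p.g * k / (p.N0 - k)


def khat_of_k(k: float, lam: float) -> float:
    """Steady-state Treg activation ``khat = lam * k``."""
    if k < 0 or lam < 0:
        raise ValueError("k and lam must be >= 0")
    return lam * k


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelInfo:
    """Uniform access to a model: ``rhs(y, p, drive)`` where ``drive`` is
    beta for full models and k for reduced ones."""

    model_id: str
    names: tuple[str, ...]
    drive: str  # "beta" | "k"
    rhs: Callable
    jac: Callable

    @property
    def dim(self) -> int:
        return len(self.names)

    def rhs_ivp(self, p: ParameterSet, drive_value: float, lam: float | None = None):
        """Return an ``f(t, y)`` suitable for scipy integrators."""
        if self.drive == "k" and self.model_id == "reduced13":
            return lambda t, y: rhs_reduced13(y, p, drive_value, lam,
                                              allow_negative=True)
        return lambda t, y: self.rhs(y, p, drive_value, allow_negative=True)


def _mk(model_id, names, drive, rhs, jac):
    return ModelInfo(model_id, tuple(names), drive, rhs, jac)


MODELS: dict[str, ModelInfo] = {
    "model1": _mk("model1", ("T", "I"), "beta",
                  lambda y, p, beta=None, **kw: rhs_model1(y, p, **kw),
                  lambda y, p, beta=None: jac_model1(y, p)),
    "model4": _mk("model4", ("N", "T", "I"), "beta", rhs_model4, jac_model4),
    "model10": _mk("model10", ("N", "T", "I"), "beta", rhs_model10, jac_model10),
    "model13": _mk("model13", ("N", "Nhat", "T", "R", "I"), "beta",
                   rhs_model13, jac_model13),
    "reduced4": _mk("reduced4", ("T", "I"), "k", rhs_reduced4, jac_reduced4),
    "reduced10": _mk("reduced10", ("T", "I"), "k", rhs_reduced10, jac_reduced10),
    "reduced13": _mk("reduced13", ("T", "R", "I"), "k",
                     rhs_reduced13, jac_reduced13),
}


def get_model(model_id: str) -> ModelInfo:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; choose from {sorted(MODELS)}"
        ) from None
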