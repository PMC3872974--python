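"""Regime thresholds of the Treg-controlled immune response.

The reduced Tconv/Treg/IL-2 system organizes its behaviour around two
moving landmarks in the activation rate k:

* the fold ``k_i`` where the low (quiescent) equilibrium branch is
  annihilated — below it stimulation cannot initiate a response;
* the Hopf point ``k_s`` on the Treg-controlled branch T4 — above it the
  response is damped into a small chronic equilibrium (over-suppression).

Between the two, trajectories from zero initial conditions settle into a
stable limit cycle: the effective, oscillating immune response. Raising
the relative Treg renewal ``lam`` narrows the window until fold and Hopf
merge at ``lam_th``; beyond it no activation level initiates a response.

The authoritative classification is trajectory-based (integrate from zero
initial conditions, ask whether the response initiates), matching how the
regime diagrams are constructed; the eigenvalue route (fold/Hopf landmarks)
is computed independently and used as a cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .equilibria import find_equilibria
from .models import beta_of_k, k_of_beta
from .params import ParameterSet
from .simulation import (ResponseConfig, ResponseSummary, detect_response,
                         integrate)

__all__ = [
    "LimitCycleSummary", "KThresholds", "RegimeReport",
    "probe_response", "k_fold_reduced13", "k_hopf_reduced13",
    "find_k_thresholds", "find_lambda_th", "lambda_th_eigen",
    "scan_limit_cycles", "regime_map", "classify_regime",
]

log = logging.getLogger(__name__)

_DEFAULT_HORIZON = 2000.0
_MAX_HORIZON = 8000.0


@dataclass(frozen=True)
class LimitCycleSummary:
    """Envelope and period of a sustained oscillation at one k."""

    k: float
    T_min: float
    T_max: float
    period: float
    n_peaks: int
    ambiguous: bool = False


@dataclass(frozen=True)
class KThresholds:
    """Activation-rate regime boundaries at one lam.

    ``k_i``/``k_s`` are the trajectory-defined initiation and
    over-suppression thresholds; ``k_fold``/``k_hopf`` are the fold and
    Hopf landmarks from the equilibrium structure, kept as an independent
    cross-check (they agree to well under a percent away from lam_th).
    """

    lam: float
    exists: bool
    k_i: float = math.nan
    k_s: float = math.nan
    k_fold: float = math.nan
    k_hopf: float = math.nan


@dataclass(frozen=True)
class RegimeReport:
    lam: float
    N0: float
    lambda_th: float
    k_i: float
    k_s: float
    beta_i: float  # nan when it does not exist
    beta_s: float
    beta_i_exists: bool
    beta_s_exists: bool
    regime: str


# ---------------------------------------------------------------------------
# equilibrium-structure landmarks
# ---------------------------------------------------------------------------

def _n_equilibria(p: ParameterSet, k: float, lam: float) -> int:
    return len(find_equilibria("reduced13", p, k=k, lam=lam))


def k_fold_reduced13(p: ParameterSet, lam: float,
                     k_range: tuple[float, float] = (1e-3, 16.0),
                     rtol: float = 1e-8) -> float | None:
    """Locate the fold where the equilibrium count drops (5 -> 3).

    Bisection on the count of real equilibria of the reduced system.
    Returns None when the count does not change over ``k_range``.
    """
    lo, hi = k_range
    n_lo, n_hi = _n_equilibria(p, lo, lam), _n_equilibria(p, hi, lam)
    if n_lo <= n_hi:
        return None
    while hi - lo > rtol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if _n_equilibria(p, mid, lam) >= n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _t4_max_re(p: ParameterSet, k: float, lam: float) -> float:
    """Leading eigenvalue real part on the Treg-controlled branch T4."""
    pts = find_equilibria("reduced13", p, k=k, lam=lam)
    t4 = [q for q in pts if q.label == "T4"]
    if not t4:
        phys = sorted((q for q in pts if q.physical), key=lambda q: q.T)
        if not phys:
            return math.nan
        t4 = [phys[-1]]
    return float(np.max(t4[0].eigenvalues.real))


def k_hopf_reduced13(p: ParameterSet, lam: float,
                     k_fold: float | None = None,
                     k_max: float = 64.0) -> float | None:
    """Upper Hopf point on T4: where its unstable focus stabilizes."""
    if k_fold is None:
        k_fold = k_fold_reduced13(p, lam)
    if k_fold is None:
        return None
    k_lo = k_fold * (1.0 + 1e-9)
    f_lo = _t4_max_re(p, k_lo, lam)
    if not math.isfinite(f_lo) or f_lo <= 0:
        return None
    k_hi = k_lo
    f_hi = f_lo
    while f_hi > 0 and k_hi < k_max:
        k_hi = min(2.0 * k_hi, k_max)
        f_hi = _t4_max_re(p, k_hi, lam)
    if f_hi > 0 or not math.isfinite(f_hi):
        return None
    return float(brentq(lambda k: _t4_max_re(p, k, lam), k_lo, k_hi,
                        xtol=1e-10, rtol=1e-12))


def lambda_th_eigen(p: ParameterSet,
                    lam_bracket: tuple[float, float] = (1e-4, 0.05),
                    tol: float = 1e-7) -> float:
    """Treg-renewal threshold from the equilibrium structure alone.

    The oscillatory window exists iff the Treg-controlled branch is
    unstable immediately above the fold; ``lam_th`` is where that window
    closes (fold and Hopf merge). Independent of the trajectory-based
    route in :func:`find_lambda_th` — the two are cross-checked in the
    test suite.
    """

    def window_exists(lam: float) -> bool:
        kf = k_fold_reduced13(p, lam)
        if kf is None:
            return False
        re = _t4_max_re(p, kf * (1.0 + 1e-7), lam)
        return math.isfinite(re) and re > 0

    lo, hi = lam_bracket
    if not window_exists(lo):
        raise ValueError(f"no oscillatory window at lam={lo}; widen the bracket")
    if window_exists(hi):
        raise ValueError(f"oscillatory window persists at lam={hi}; widen the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if window_exists(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# trajectory probes
# ---------------------------------------------------------------------------

def probe_response(p: ParameterSet, k: float, lam: float,
                   config: ResponseConfig | None = None,
                   horizon: float = _DEFAULT_HORIZON) -> ResponseSummary:
    """Integrate the reduced system from zero initial conditions and
    classify the outcome, extending the horizon when the verdict is
    ambiguous (slow transients near the regime boundaries)."""
    cfg = config or ResponseConfig()
    h = horizon
    while True:
        traj = integrate("reduced13", p, k=k, lam=lam, t_span=(0.0, h),
                         n_samples=max(2001, int(2 * h) + 1))
        summary = detect_response(traj, cfg, p=p, k=k, lam=lam)
        if not summary.ambiguous or h >= _MAX_HORIZON:
            return summary
        h = min(2.0 * h, _MAX_HORIZON)


def _candidate_ks(p: ParameterSet, lam: float, k_max: float) -> list[float]:
    """Probe activation rates: fold-guided offsets when the fold exists
    (the oscillatory window, if any, opens at the fold), else a log grid."""
    kf = k_fold_reduced13(p, lam, k_range=(1e-3, max(16.0, k_max)))
    if kf is None:
        return list(np.geomspace(max(1e-2, 1e-3 * k_max), k_max, 12))
    deltas = (1e-3, 3e-3, 1e-2, 3e-2, 0.1, 0.3, 1.0, 3.0)
    ks = [kf * (1.0 + d) for d in deltas]
    return [k for k in ks if k <= max(k_max, kf * 1.01)]


def _any_response(p: ParameterSet, lam: float, cfg: ResponseConfig,
                  k_max: float) -> bool:
    return any(probe_response(p, k, lam, cfg).initiated
               for k in _candidate_ks(p, lam, k_max))


def find_lambda_th(p: ParameterSet, config: ResponseConfig | None = None,
                   tol: float = 1e-5,
                   lam_bracket: tuple[float, float] = (0.004, 0.025),
                   k_max: float | None = None) -> float:
    """Treg-renewal threshold above which no activation level initiates
    a response.

    Bisection on lam of the trajectory predicate "some k initiates a
    response from zero initial conditions", with fold-guided probe
    activation rates. By construction the result depends only on the
    reduced system: it is independent of g and N0.
    """
    cfg = config or ResponseConfig()
    k_max = 2.0 * p.N0 if k_max is None else k_max
    lo, hi = lam_bracket
    for _ in range(8):
        if _any_response(p, lo, cfg, k_max):
            break
        log.warning("no response at lam=%g; widening bracket downwards", lo)
        lo /= 2.0
    else:
        raise ValueError("no responsive lam found; check parameters")
    for _ in range(8):
        if not _any_response(p, hi, cfg, k_max):
            break
        log.warning("response persists at lam=%g; widening bracket upwards", hi)
        hi *= 2.0
    else:
        raise ValueError("no unresponsive lam found; check parameters")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _any_response(p, mid, cfg, k_max):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_k_thresholds(p: ParameterSet, lam: float,
                      config: ResponseConfig | None = None,
                      rtol: float = 1e-3,
                      k_max: float | None = None) -> KThresholds:
    """Locate the initiation (k_i) and over-suppression (k_s) thresholds.

    Both are found by bisection on the binary outcome of zero-initial-
    condition trajectory probes; the fold and Hopf landmarks are attached
    for cross-validation. When no probe initiates a response
    (lam above threshold) the report carries ``exists=False``.
    """
    cfg = config or ResponseConfig()
    k_max = 2.0 * p.N0 if k_max is None else k_max
    kf = k_fold_reduced13(p, lam, k_range=(1e-3, max(16.0, k_max)))
    kh = k_hopf_reduced13(p, lam, k_fold=kf) if kf is not None else None

    candidates = _candidate_ks(p, lam, k_max)
    k_on = next((k for k in candidates
                 if probe_response(p, k, lam, cfg).initiated), None)
    if k_on is None:
        return KThresholds(lam=lam, exists=False,
                           k_fold=kf if kf is not None else math.nan,
                           k_hopf=kh if kh is not None else math.nan)

    # k_i: last quiescent k below k_on
    lo = (0.5 * kf) if kf is not None else 0.25 * k_on
    while probe_response(p, lo, lam, cfg).initiated:
        lo *= 0.5
        if lo < 1e-9:
            break
    hi = k_on
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if probe_response(p, mid, lam, cfg).initiated:
            hi = mid
        else:
            lo = mid
    k_i = 0.5 * (lo + hi)

    # k_s: first k above the window with no sustained response
    lo = k_on
    hi = max(k_on * 1.5, (kh * 1.05) if kh is not None else k_on * 2.0)
    for _ in range(20):
        if not probe_response(p, hi, lam, cfg).initiated:
            break
        lo, hi = hi, hi * 1.5
    else:
        log.warning("response persists up to k=%g; k_s not bracketed", hi)
        return KThresholds(lam=lam, exists=True, k_i=k_i, k_s=math.inf,
                           k_fold=kf or math.nan, k_hopf=kh or math.nan)
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if probe_response(p, mid, lam, cfg).initiated:
            lo = mid
        else:
            hi = mid
    k_s = 0.5 * (lo + hi)

    if kf is not None and abs(k_i - kf) > 0.01 * kf:
        log.warning("k_i=%g deviates from fold %g by >1%%", k_i, kf)
    if kh is not None and abs(k_s - kh) > 0.01 * kh:
        log.warning("k_s=%g deviates from Hopf %g by >1%%", k_s, kh)
    return KThresholds(lam=lam, exists=True, k_i=k_i, k_s=k_s,
                       k_fold=kf if kf is not None else math.nan,
                       k_hopf=kh if kh is not None else math.nan)


# ---------------------------------------------------------------------------
# limit cycles
# ---------------------------------------------------------------------------

def scan_limit_cycles(p: ParameterSet, lam: float, k_grid,
                      config: ResponseConfig | None = None,
                      horizon: float = _DEFAULT_HORIZON,
                      ) -> list[LimitCycleSummary]:
    """Oscillation envelope (min/max activated T cells) and period across
    a grid of activation rates.

    Each k is probed from zero initial conditions; only sustained
    oscillations are reported (quiescent or damped outcomes are skipped,
    borderline detections are flagged ambiguous). Within the oscillatory
    window both the envelope maximum and the period shrink as activation
    grows: stronger Treg co-activation suppresses each successive burst
    earlier.
    """
    cfg = config or ResponseConfig()
    out = []
    for k in np.atleast_1d(np.asarray(k_grid, dtype=float)):
        summary = probe_response(p, float(k), lam, cfg, horizon=horizon)
        if not summary.sustained_oscillation:
            continue
        out.append(LimitCycleSummary(
            k=float(k), T_min=summary.T_min, T_max=summary.T_max,
            period=summary.period, n_peaks=summary.n_oscillation_peaks,
            ambiguous=summary.ambiguous))
    return out


# ---------------------------------------------------------------------------
# regimes
# ---------------------------------------------------------------------------

def _beta_threshold(p: ParameterSet, k_thr: float) -> tuple[float, bool]:
    if math.isfinite(k_thr) and p.N0 > k_thr:
        return beta_of_k(p, k_thr), True
    return math.nan, False


def classify_regime(p: ParameterSet, lam: float, N0: float | None = None,
                    beta: float | None = None,
                    thresholds: KThresholds | None = None,
                    lambda_th: float | None = None,
                    config: ResponseConfig | None = None,
                    boundary_rtol: float = 1e-3) -> str:
    """Label the immune outcome for a given (lam, N0, beta).

    Returns ``unresponsive`` (lam at or above the renewal threshold),
    ``subcritical`` (activation below k_i), ``effective_oscillatory``
    (inside the window), ``over_suppressed`` (above k_s), or ``boundary``
    when the mapped activation rate is within ``boundary_rtol`` of a
    threshold. Expensive intermediates can be passed in to avoid
    recomputation.
    """
    cfg = config or ResponseConfig()
    pp = p if N0 is None else p.replace(N0=N0)
    beta = pp.beta if beta is None else beta
    if lambda_th is None:
        lambda_th = find_lambda_th(pp, cfg)
    if lam >= lambda_th:
        return "unresponsive"
    if thresholds is None:
        thresholds = find_k_thresholds(pp, lam, cfg)
    if not thresholds.exists:
        return "unresponsive"
    k = k_of_beta(pp, beta)
    for thr in (thresholds.k_i, thresholds.k_s):
        if math.isfinite(thr) and abs(k - thr) <= boundary_rtol * thr:
            return "boundary"
    if k < thresholds.k_i:
        return "subcritical"
    if k < thresholds.k_s:
        return "effective_oscillatory"
    return "over_suppressed"


def regime_map(p: ParameterSet, lam_grid, N0_grid,
               config: ResponseConfig | None = None,
               lambda_th: float | None = None) -> list[RegimeReport]:
    """Chart the (lam, N0) plane into the four response regions.

    A: lam above the renewal threshold — unresponsive for every N0 and
    beta. For lam below it: B when N0 <= k_i (no stimulation can
    initiate), C when k_i < N0 <= k_s (initiation threshold beta_i exists,
    over-suppression unreachable), D when N0 > k_s (both beta_i and
    beta_s exist). k thresholds depend on lam only, so they are computed
    once per lam value.
    """
    cfg = config or ResponseConfig()
    if lambda_th is None:
        lambda_th = find_lambda_th(p, cfg)
    reports = []
    for lam in np.atleast_1d(np.asarray(lam_grid, dtype=float)):
        lam = float(lam)
        thr = (find_k_thresholds(p, lam, cfg)
               if lam < lambda_th else KThresholds(lam=lam, exists=False))
        for N0 in np.atleast_1d(np.asarray(N0_grid, dtype=float)):
            N0 = float(N0)
            pp = p.replace(N0=N0)
            if lam >= lambda_th or not thr.exists:
                region = "A"
                bi = bs = math.nan
                bi_ex = bs_ex = False
            else:
                bi, bi_ex = _beta_threshold(pp, thr.k_i)
                bs, bs_ex = _beta_threshold(pp, thr.k_s)
                if N0 <= thr.k_i:
                    region = "B"
                elif N0 <= thr.k_s:
                    region = "C"
                else:
                    region = "D"
            reports.append(RegimeReport(
                lam=lam, N0=N0, lambda_th=lambda_th,
                k_i=thr.k_i, k_s=thr.k_s,
                beta_i=bi, beta_s=bs,
                beta_i_exists=bi_ex, beta_s_exists=bs_ex,
                regime={"A": "unresponsive", "B": "subcritical",
                        "C": "initiation_only", "D": "full_range"}[region]
                + f" ({region})",
            ))
    return reports
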