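import math

import numpy as np
import pytest

from tregdyn import (c_minus, condition_positive_T2,
                     equilibria_model1_closed_form, find_equilibria,
                     initiation_bounds, jacobian_and_classify, k_minus,
                     k_of_beta, multistart_equilibria)
from tregdyn.models import rhs_reduced10, rhs_reduced13

from conftest import random_positive_params


class TestClosedFormModel1:
    def test_canonical_values(self, p):
        pts = equilibria_model1_closed_form(p)
        assert len(pts) == 2
        origin, t2 = pts
        assert origin.state == pytest.approx([0.0, 0.0])
        # b f/(ad-be) = 0.1/0.003 ; b/a = 0.25
        assert t2.state == pytest.approx([100.0 / 3.0, 0.25])

    def test_origin_stable_threshold_saddle(self, p):
        origin, t2 = equilibria_model1_closed_form(p)
        assert origin.stability == "stable"
        assert sorted(origin.eigenvalues.real) == pytest.approx(
            sorted([-p.b, -p.f]))
        assert t2.stability == "saddle"
        assert t2.n_unstable == 1

    def test_degenerate_quality_condition(self, p):
        pdeg = p.replace(a=0.1, d=0.01, b=0.1, e=0.01)
        pts = equilibria_model1_closed_form(pdeg)
        assert len(pts) == 1
        assert pts[0].note is not None

    def test_quality_condition(self, p):
        assert condition_positive_T2(p)  # 0.004 - 0.001 > 0
        assert not condition_positive_T2(p.replace(a=0.1, d=0.01))

    def test_matches_multistart_numerics(self, p, rng):
        """Closed form vs independent multi-start root finding."""
        for i, ps in enumerate(random_positive_params(rng, 10)):
            closed = {q.label: q for q in equilibria_model1_closed_form(ps)}
            numeric = multistart_equilibria("model1", ps, seed=i)
            t2 = closed["T2"].state
            best = min(numeric, key=lambda q: np.max(np.abs(q.state - t2)))
            scale = 1.0 + np.max(np.abs(t2))
            assert np.max(np.abs(best.state - t2)) < 1e-10 * scale

    def test_no_positive_nontrivial_point_when_condition_fails(self, rng):
        ps = random_positive_params(rng, 3, require_quality=True)
        for p_ in ps:
            bad = p_.replace(a=p_.b * p_.e / p_.d * 0.5)  # ad < be
            numeric = multistart_equilibria("model1", bad, seed=0)
            assert all(q.T < 1e-8 for q in numeric if q.physical)


class TestThresholds:
    def test_k_minus_canonical(self, p):
        km = k_minus(p)
        # (adf/e^2)(1-sqrt(1-be/ad))^2 with ad=4e-3, be=1e-3
        assert km == pytest.approx(40.0 * (1 - math.sqrt(0.75)) ** 2)
        assert km == pytest.approx(0.718, abs=5e-4)

    def test_k_minus_is_discriminant_root(self, rng):
        """k- must be exactly where the reduced quadratic loses real roots."""
        for ps in random_positive_params(rng, 10):
            km = k_minus(ps)
            ad_be = ps.a * ps.d - ps.b * ps.e

            def disc(k):
                return (k * ps.e - ps.b * ps.f) ** 2 - 4 * ad_be * k * ps.f

            assert disc(km) == pytest.approx(0.0, abs=1e-9 * (ps.b * ps.f) ** 2)
            assert disc(km * 0.999) > 0  # equilibria exist just below
            assert disc(km * 1.001) < 0  # none just above

    def test_k_minus_scaling_law(self, p):
        """Rescaling d and e together scales the fold by 1/s.

        Substituting (d, e) -> (s d, s e) into the discriminant of the
        reduced quadratic shows k -> k/s maps solutions to solutions, so
        the fold moves as k- / s; the closed form must follow suit.
        """
        for s in (0.3, 2.0, 7.0):
            ps = p.replace(d=p.d * s, e=p.e * s)
            assert k_minus(ps) == pytest.approx(k_minus(p) / s, rel=1e-12)

    def test_k_minus_vanishes_with_death_rate(self, p):
        kms = [k_minus(p.replace(b=b)) for b in (1e-2, 1e-4, 1e-6)]
        assert kms[0] > kms[1] > kms[2]
        assert kms[2] < 1e-4

    def test_k_minus_requires_quality_condition(self, p):
        with pytest.raises(ValueError):
            k_minus(p.replace(a=0.01))

    def test_c_minus_canonical(self, p):
        assert c_minus(p) == pytest.approx(1e-3)
        assert p.c < c_minus(p)  # canonical set sits in the saturated regime

    def test_c_minus_closes_saturated_branch(self, p):
        cm = c_minus(p)
        below = find_equilibria("reduced10", p.replace(c=cm * 0.98), k=0.0)
        above = find_equilibria("reduced10", p.replace(c=cm * 1.02), k=0.0)
        assert sum(q.T > 1.0 for q in below) == 2  # saturated pair exists
        assert sum(q.T > 1.0 for q in above) == 0

    def test_c_minus_limit_no_death(self, p):
        assert c_minus(p.replace(b=0.0)) == pytest.approx(
            p.a * p.d / p.f, rel=1e-12)

    def test_initiation_bounds_consistency(self, p):
        thr = initiation_bounds(p)
        assert thr.beta_init_exists and thr.g == p.g
        # mapping the bound through the activation identity recovers k-
        assert k_of_beta(p, thr.beta_init) == pytest.approx(thr.k_minus,
                                                            rel=1e-12)

    def test_initiation_impossible_for_small_renewal(self, p):
        thr = initiation_bounds(p.replace(N0=0.5))  # N0 < k-
        assert not thr.beta_init_exists
        assert math.isinf(thr.beta_init)

    def test_bound_vanishes_for_large_renewal(self, p):
        b1 = initiation_bounds(p.replace(N0=10.0)).beta_init
        b2 = initiation_bounds(p.replace(N0=1000.0)).beta_init
        assert b2 < b1 and b2 < 1e-3


class TestFindEquilibria:
    def test_model1_numeric_equals_closed_form(self, p):
        closed = equilibria_model1_closed_form(p)
        numeric = find_equilibria("model1", p)
        assert len(closed) == len(numeric)
        for qc, qn in zip(closed, numeric):
            assert qn.state == pytest.approx(qc.state, rel=1e-10, abs=1e-12)

    def test_reduced13_origin_at_zero_influx(self, p):
        pts = find_equilibria("reduced13", p, k=0.0, lam=0.006)
        origin = min(pts, key=lambda q: abs(q.T) + abs(q.state[1]))
        assert np.max(np.abs(origin.state)) < 1e-12

    def test_reduced13_count_transition_five_to_three(self, p):
        """Single 5 -> 3 transition in the equilibrium count along k."""
        ks = np.linspace(0.05, 8.0, 60)
        counts = [len(find_equilibria("reduced13", p, k=k, lam=0.006))
                  for k in ks]
        assert set(counts) == {5, 3}
        flips = np.nonzero(np.diff(counts))[0]
        assert len(flips) == 1
        assert counts[0] == 5 and counts[-1] == 3

    def test_reduced13_residuals_tiny(self, p):
        for k in (0.3, 1.0, 5.0):
            for q in find_equilibria("reduced13", p, k=k, lam=0.006):
                scale = 1.0 + np.max(np.abs(q.state))
                assert q.residual < 1e-9 * scale

    def test_reduced13_matches_multistart(self, p):
        """Polynomial elimination vs the Sobol multi-start oracle."""
        for k in (0.3, 1.5):
            poly = find_equilibria("reduced13", p, k=k, lam=0.006)
            ms = multistart_equilibria("reduced13", p, k=k, lam=0.006,
                                       n_starts=256, seed=3)
            # every multistart root matches a polynomial root
            for qm in ms:
                dist = min(np.max(np.abs(qm.state - qp.state)) /
                           (1 + np.max(np.abs(qp.state))) for qp in poly)
                assert dist < 1e-8

    def test_full_model13_carries_naive_steady_states(self, p):
        pts = find_equilibria("model13", p.replace(beta=0.06))
        Nst = p.N0 / (p.g + 0.06)
        for q in pts:
            assert q.state[0] == pytest.approx(Nst)
            assert q.state[1] == pytest.approx(p.lam * Nst)

    def test_negative_branch_flagged_not_discarded(self, p):
        pts = find_equilibria("reduced13", p, k=1.0, lam=0.006)
        t5 = [q for q in pts if q.label == "T5"]
        assert t5 and not t5[0].physical

    def test_reduced_models_require_k(self, p):
        with pytest.raises(ValueError, match="activation rate"):
            find_equilibria("reduced13", p)


class TestJacobianAndClassify:
    def test_origin_of_model1_diagonal(self, p):
        q = jacobian_and_classify("model1", [0.0, 0.0], p)
        assert sorted(q.eigenvalues.real) == pytest.approx(
            sorted([-p.b, -p.f]))
        assert q.stability == "stable"

    def test_rejects_non_equilibrium(self, p):
        with pytest.raises(ValueError, match="residual"):
            jacobian_and_classify("model1", [10.0, 10.0], p)

    def test_t4_stability_flips_across_hopf(self, p):
        pts = {q.label: q for q in find_equilibria("reduced13", p, k=1.5,
                                                   lam=0.006)}
        assert pts["T4"].n_unstable == 2  # unstable focus in the window
        pts_hi = {q.label: q for q in find_equilibria("reduced13", p, k=8.0,
                                                      lam=0.006)}
        assert pts_hi["T4"].stability == "stable"
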