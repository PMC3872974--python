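import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregdyn import (beta_of_k, integrate, k_of_beta, khat_of_k, rhs_model1,
                     rhs_model4, rhs_model10, rhs_model13, rhs_reduced10,
                     rhs_reduced13, table1)
from tregdyn.models import (MODELS, get_model, jac_model13, jac_reduced13,
                            rhs_reduced4)


class TestHandEvaluations:
    """Right-hand sides against independent hand evaluation."""

    def test_model1_origin_is_equilibrium(self, p):
        assert rhs_model1([0.0, 0.0], p) == pytest.approx([0.0, 0.0])

    def test_model1_unit_state(self, p):
        # aIT - bT = 0.4 - 0.1 ; dT - eIT - fI = 0.01 - 0.01 - 1
        assert rhs_model1([1.0, 1.0], p) == pytest.approx([0.3, -1.0])

    def test_model1_threshold_state_is_stationary(self, p):
        T2 = p.b * p.f / (p.a * p.d - p.b * p.e)
        I2 = p.b / p.a
        assert np.max(np.abs(rhs_model1([T2, I2], p))) < 1e-12

    def test_model4_homeostatic_state(self, p):
        assert rhs_model4([p.N0 / p.g, 0.0, 0.0], p, beta=0.0) == \
            pytest.approx([0.0, 0.0, 0.0])

    def test_model4_renewal_only_from_empty(self, p):
        assert rhs_model4([0.0, 0.0, 0.0], p, beta=0.0) == \
            pytest.approx([4.0, 0.0, 0.0])

    def test_model10_fratricide_term(self, p):
        # dT/dt = -b*100 - c*100^2 = -10.1 at (N=0, T=100, I=0)
        out = rhs_model10([0.0, 100.0, 0.0], p, beta=0.0)
        assert out[1] == pytest.approx(-10.1)

    def test_model13_homeostatic_state(self, p):
        lam = p.lam
        y = [p.N0 / p.g, lam * p.N0 / p.g, 0.0, 0.0, 0.0]
        assert np.max(np.abs(rhs_model13(y, p, beta=0.0))) == 0.0

    def test_negative_state_rejected_without_flag(self, p):
        with pytest.raises(ValueError, match="negative"):
            rhs_model1([-1.0, 0.0], p)
        assert rhs_model1([-1.0, 0.0], p, allow_negative=True)[0] == \
            pytest.approx(0.1)


class TestNesting:
    """Each model reduces exactly to its predecessor in the right limit."""

    def test_model10_reduces_to_model4_when_c_zero(self, p, rng):
        p0 = p.replace(c=0.0)
        for _ in range(10):
            y = rng.uniform(0, 50, size=3)
            assert rhs_model10(y, p0, beta=0.3) == \
                pytest.approx(rhs_model4(y, p0, beta=0.3))

    def test_model13_reduces_to_model10_without_tregs(self, p, rng):
        p0 = p.replace(gamma=0.0, lam=0.0)
        for _ in range(10):
            y3 = rng.uniform(0, 50, size=3)  # (N, T, I)
            y5 = np.array([y3[0], 0.0, y3[1], 0.0, y3[2]])
            full = rhs_model13(y5, p0, beta=0.3)
            sub = rhs_model10(y3, p0, beta=0.3)
            assert full[[0, 2, 4]] == pytest.approx(sub)
            assert full[[1, 3]] == pytest.approx([0.0, 0.0])

    def test_model4_reduces_to_model1(self, p, rng):
        p0 = p.replace(N0=0.0, beta=0.0)
        for _ in range(10):
            y = rng.uniform(0, 50, size=2)
            assert rhs_model4([0.0, *y], p0)[1:] == \
                pytest.approx(rhs_model1(y, p0))

    def test_reduced13_matches_full_at_naive_steady_state(self, p, rng):
        beta = 0.25
        k = k_of_beta(p, beta)
        Nst = p.N0 / (p.g + beta)
        for _ in range(10):
            y = rng.uniform(0, 50, size=3)  # (T, R, I)
            full = rhs_model13([Nst, p.lam * Nst, *y], p, beta=beta)
            red = rhs_reduced13(y, p, k)
            assert full[2:] == pytest.approx(red)
            assert full[:2] == pytest.approx([0.0, 0.0])

    def test_reduced13_reduces_to_reduced10_without_tregs(self, p, rng):
        p0 = p.replace(gamma=0.0, lam=0.0)
        for _ in range(5):
            y = rng.uniform(0, 50, size=2)
            red13 = rhs_reduced13([y[0], 0.0, y[1]], p0, 0.7)
            red10 = rhs_reduced10(y, p0, 0.7)
            assert red13[[0, 2]] == pytest.approx(red10)

    def test_reduced13_origin_stationary_at_zero_influx(self, p):
        assert np.max(np.abs(rhs_reduced13([0.0, 0.0, 0.0], p, 0.0))) == 0.0


@pytest.fixture(scope="module")
def sym13():
    import sympy as sp

    N, Nh, T, R, I = sp.symbols("N Nh T R I")
    a, b, c, d, e, f, g, beta, gam, eps, N0, lam = sp.symbols(
        "a b c d e f g beta gamma epsilon N0 lam")
    rhs = sp.Matrix([
        N0 - g * N - beta * N,
        lam * N0 - g * Nh - beta * Nh,
        a * I * T - b * T - c * T**2 - gam * R * T + beta * N,
        eps * a * I * R - b * R + beta * Nh,
        d * T - e * I * (T + R) - f * I,
    ])
    state = sp.Matrix([N, Nh, T, R, I])
    params = (a, b, c, d, e, f, g, beta, gam, eps, N0, lam)
    fn = sp.lambdify((state, params), rhs, "numpy")
    jfn = sp.lambdify((state, params), rhs.jacobian(state), "numpy")
    return fn, jfn


class TestSymbolicOracle:
    """Generic states against sympy-differentiated forms of the printed
    systems, for both the rhs and the analytic Jacobians."""

    def test_model13_rhs_and_jacobian(self, p, rng, sym13):
        fn, jfn = sym13
        beta = 0.37
        vals = (p.a, p.b, p.c, p.d, p.e, p.f, p.g, beta, p.gamma,
                p.epsilon, p.N0, p.lam)
        for _ in range(5):
            y = rng.uniform(0, 80, size=5)
            assert rhs_model13(y, p, beta=beta) == pytest.approx(
                np.asarray(fn(y, vals)).ravel(), rel=1e-12)
            assert jac_model13(y, p, beta=beta) == pytest.approx(
                np.asarray(jfn(y, vals)), rel=1e-12)

    @pytest.mark.parametrize("model_id", sorted(MODELS))
    def test_jacobian_matches_finite_difference(self, p, rng, model_id):
        info = get_model(model_id)
        drive = 0.3
        y0 = rng.uniform(1.0, 30.0, size=info.dim)
        jac = info.jac(y0, p, drive)
        eps_fd = 1e-6
        for j in range(info.dim):
            dy = np.zeros(info.dim)
            dy[j] = eps_fd * max(1.0, abs(y0[j]))
            num = (info.rhs(y0 + dy, p, drive) -
                   info.rhs(y0 - dy, p, drive)) / (2 * dy[j])
            assert num == pytest.approx(jac[:, j], rel=1e-5, abs=1e-8)


class TestActivationIdentities:
    def test_k_of_beta_zero(self, p):
        assert k_of_beta(p, 0.0) == 0.0

    def test_k_of_beta_saturates_at_N0(self, p):
        assert k_of_beta(p, 1e9) == pytest.approx(p.N0, rel=1e-8)
        assert k_of_beta(p, p.g) == pytest.approx(p.N0 / 2)

    def test_k_monotone_in_beta(self, p):
        betas = np.linspace(0, 10, 50)
        ks = [k_of_beta(p, b) for b in betas]
        assert np.all(np.diff(ks) > 0)
        assert max(ks) < p.N0

    def test_beta_of_k_inverts(self, p):
        for k in (0.1, 0.718, 3.0):
            assert k_of_beta(p, beta_of_k(p, k)) == pytest.approx(k)

    def test_khat_is_lam_times_k(self, p):
        assert khat_of_k(0.7, 0.02) == pytest.approx(0.014)
        assert khat_of_k(5.0, 0.0) == 0.0
        assert khat_of_k(k_of_beta(p, 0.3), p.lam) == pytest.approx(
            p.lam * 0.3 * p.N0 / (p.g + 0.3))

    def test_undefined_at_g_beta_zero(self, p):
        with pytest.raises(ValueError):
            k_of_beta(p.replace(g=0.0), 0.0)


class TestTrajectoryProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(beta=st.floats(0.0, 2.0), n0=st.floats(0.0, 200.0),
           nh0=st.floats(0.0, 50.0))
    def test_naive_compartments_relax_to_closed_form(self, beta, n0, nh0):
        """N and Nhat follow linear dynamics with an exponential solution."""
        p = table1()
        t_end = 30.0
        traj = integrate("model13", p, t_span=(0.0, t_end),
                         init=[n0, nh0, 0.0, 0.0, 0.0],
                         schedule=None if beta == 0 else
                         __import__("tregdyn").StimulationSchedule.constant(
                             beta, t_end))
        r = p.g + beta
        Ninf = p.N0 / r
        expect = Ninf + (n0 - Ninf) * np.exp(-r * traj.t)
        assert traj.component("N") == pytest.approx(expect, rel=1e-6, abs=1e-6)
        Nhinf = p.lam * p.N0 / r
        expect_h = Nhinf + (nh0 - Nhinf) * np.exp(-r * traj.t)
        assert traj.component("Nhat") == pytest.approx(expect_h, rel=1e-6,
                                                       abs=1e-6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(k=st.floats(0.0, 4.0), lam=st.floats(0.0, 0.03),
           seed=st.integers(0, 100))
    def test_nonnegative_orthant_invariance(self, k, lam, seed):
        """Populations started nonnegative never go meaningfully negative."""
        rng = np.random.default_rng(seed)
        p = table1()
        init = rng.uniform(0, 20, size=3)
        traj = integrate("reduced13", p, k=k, lam=lam, t_span=(0.0, 300.0),
                         init=init, n_samples=601)
        assert traj.y.min() > -1e-9
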