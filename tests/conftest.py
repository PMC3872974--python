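import numpy as np
import pytest

from tregdyn import ResponseConfig, find_lambda_th, table1


@pytest.fixture(scope="session")
def p():
    """Canonical parameter set (responsive case, lam=0.006)."""
    return table1()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231226)


def random_positive_params(rng, n, require_quality=True):
    """Seeded random parameter sets around the canonical values.

    Each rate is scaled log-uniformly in [1/2, 2] of its canonical value;
    sets violating the clone-quality condition a*d > b*e are resampled
    when ``require_quality``.
    """
    base = table1()
    out = []
    while len(out) < n:
        factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=6))
        cand = base.replace(
            a=base.a * factors[0], b=base.b * factors[1],
            c=base.c * factors[2], d=base.d * factors[3],
            e=base.e * factors[4], f=base.f * factors[5])
        if require_quality and cand.a * cand.d <= cand.b * cand.e:
            continue
        out.append(cand)
    return out


@pytest.fixture(scope="session")
def lambda_th_baseline(p):
    """Trajectory-based Treg-renewal threshold, shared across tests."""
    return find_lambda_th(p, ResponseConfig())
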