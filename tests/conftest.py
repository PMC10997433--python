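import numpy as np
import pytest

import polyflux as pf


@pytest.fixture
def chain_model():
    """Linear pathway of 3 reactions capped at [5, 10, 10]."""
    return pf.make_chain_model(3, [5.0, 10.0, 10.0])


@pytest.fixture
def branch_model():
    return pf.make_branch_model()


@pytest.fixture
def cube2():
    P, _ = pf.make_reference_polytope("cube", 2)
    return P


@pytest.fixture
def unit_square():
    """[0, 1]^2 as an H-polytope."""
    A = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
    b = np.array([1.0, 0.0, 1.0, 0.0])
    return pf.HPolytope(A, b)


def standard_errors(X, analytic_var=None):
    """Per-coordinate Monte-Carlo standard error of the mean using ESS."""
    d = X.shape[0]
    se = np.empty(d)
    for i in range(d):
        n_eff = pf.ess(X[i])
        sd = np.sqrt(analytic_var[i]) if analytic_var is not None else X[i].std()
        se[i] = sd / np.sqrt(n_eff)
    return se
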