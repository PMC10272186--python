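"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the reversible
transition-matrix oracle maximises the likelihood with a general-purpose
quasi-Newton optimizer over log-parameterised symmetric fluxes, and the
stationary-distribution oracle solves the eigenproblem via a null space.
"""

import numpy as np
import scipy.linalg
from scipy.optimize import minimize


def stationary_nullspace(T: np.ndarray) -> np.ndarray:
    """Stationary distribution as the null space of (T^T - I)."""
    ns = scipy.linalg.null_space(T.T - np.eye(T.shape[0]))
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def reversible_mle_optimizer(C: np.ndarray):
    """Reversible MLE by constrained numerical likelihood maximisation.

    Parameterises the symmetric flux matrix x_ij = exp(y_ij) on the upper
    triangle (entries with no observed counts stay zero), maximises
    sum_ij C_ij log(x_ij / x_i) with L-BFGS-B and an analytic gradient,
    with a soft gauge term pinning the arbitrary overall flux scale.
    Returns (T, pi).
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    iu = np.triu_indices(n)
    Csym = C + C.T
    mask = Csym[iu] > 0
    c = C.sum(axis=1)

    def unpack(y):
        vals = np.zeros(len(iu[0]))
        vals[mask] = np.exp(y)
        x = np.zeros((n, n))
        x[iu] = vals
        return x + x.T - np.diag(np.diag(x))

    def neg_loglik(y):
        x = unpack(y)
        xi = x.sum(axis=1)
        logT = np.where(C > 0, np.log(np.where(x > 0, x, 1.0)) - np.log(xi)[:, None], 0.0)
        return -np.sum(C * logT) + np.log(x.sum()) ** 2

    def grad(y):
        x = unpack(y)
        xi = x.sum(axis=1)
        G = Csym / np.where(x > 0, x, 1.0) - (c / xi)[:, None] - (c / xi)[None, :]
        np.fill_diagonal(
            G, C.diagonal() / np.where(np.diag(x) > 0, np.diag(x), 1.0) - c / xi
        )
        gauge = 2.0 * np.log(x.sum()) / x.sum()
        total = G - 2.0 * gauge
        np.fill_diagonal(total, np.diag(G) - gauge)
        return -(total[iu][mask]) * np.exp(y)

    x0 = Csym / Csym.sum()
    y0 = np.log(x0[iu][mask])
    res = minimize(
        neg_loglik, y0, jac=grad, method="L-BFGS-B",
        options={"maxiter": 50_000, "ftol": 1e-17, "gtol": 1e-12},
    )
    x = unpack(res.x)
    xi = x.sum(axis=1)
    return x / xi[:, None], xi / xi.sum()


def random_count_matrix(rng, n_states: int, n_counts: int = 200) -> np.ndarray:
    """A dense random count matrix with at least one count per pair."""
    T = rng.dirichlet(np.full(n_states, 0.8), size=n_states) + 0.01
    T = T / T.sum(axis=1)[:, None]
    return np.floor(rng.random((n_states, n_states)) * n_counts * T) + 1.0
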