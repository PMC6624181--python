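"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is assembled with explicit per-sample Kronecker products and
dense inverses, deliberately avoiding the vectorized code paths it checks.
"""

import numpy as np

from pharaoh_gee.collapse import standardize_design
from pharaoh_gee.gee_core import CoefficientMatrix, WeightMatrix


def toy_design(rng, n=8, genes_per_pathway=(2, 2)):
    """Small standardized design with the given pathway block sizes."""
    cols, block = [], []
    for k, tk in enumerate(genes_per_pathway):
        for t in range(tk):
            cols.append(rng.normal(size=n))
            block.append((f"pw{k + 1}", f"g{k + 1}_{t + 1}"))
    X_raw = np.column_stack([np.ones(n)] + cols)
    return standardize_design(X_raw, block, [f"pw{k + 1}" for k in range(len(genes_per_pathway))])


def init_params(design, Q, rng=None):
    kcol = design.pathway_of_column()
    if rng is None:
        w = np.full(design.T, 0.5)
        B = np.zeros((design.K + 1, Q))
    else:
        w = rng.normal(size=design.T)
        B = rng.normal(scale=0.3, size=(design.K + 1, Q))
    return (
        WeightMatrix(w_star=w, pathway_of_col=kcol, K=design.K),
        CoefficientMatrix(B=B),
    )


def working_cov_z(mu_i, R, family, phi):
    """Covariance of the eta-scale working response for one cluster, densely."""
    q = len(mu_i)
    if family == "gaussian":
        A = np.eye(q)
        G = np.eye(q)
    else:
        nu = mu_i * (1 - mu_i)
        A = np.diag(nu)
        G = np.diag(1.0 / nu)
    A_half = np.sqrt(A)
    return G @ (phi * A_half @ R @ A_half) @ G


def _mu_z(design, W, B, Y):
    F = design.X @ W.full
    eta = F @ B.B
    if Y.family == "gaussian":
        return F, eta, Y.Y
    mu = 1 / (1 + np.exp(-eta))
    return F, mu, eta + (Y.Y - mu) / (mu * (1 - mu))


def dense_update_B(design, W, B, Y, R, phi, lam_P):
    """Stacked Kronecker ridge-GLS solve for the coefficient matrix."""
    Q = Y.Q
    kp1 = design.K + 1
    F, mu, z = _mu_z(design, W, B, Y)
    A = np.zeros((kp1 * Q, kp1 * Q))
    rhs = np.zeros(kp1 * Q)
    for i in range(design.N):
        Qi = np.kron(F[i][None, :], np.eye(Q)).reshape(Q, kp1 * Q)
        Vinv = np.linalg.inv(working_cov_z(mu[i], R.R, Y.family, phi))
        A += Qi.T @ Vinv @ Qi
        rhs += Qi.T @ Vinv @ z[i]
    pen = np.full(kp1 * Q, lam_P)
    pen[:Q] = 0.0  # intercept row unpenalized
    return np.linalg.solve(A + np.diag(pen), rhs).reshape(kp1, Q)


def dense_update_W(design, W, B, Y, R, phi, lam_G):
    """Stacked solve for the free weights via the full Kronecker design."""
    Q = Y.Q
    kp1 = design.K + 1
    kcol = design.pathway_of_column()
    F, mu, z = _mu_z(design, W, B, Y)
    free_cols = [(t + 1) * kp1 + (kcol[t] + 1) for t in range(design.T)]
    A = np.zeros((design.T, design.T))
    rhs = np.zeros(design.T)
    for i in range(design.N):
        M_full = np.kron(design.X[i][None, :], B.B.T).reshape(Q, (design.T + 1) * kp1)
        Mi = M_full[:, free_cols]
        offset = M_full[:, 0]  # fixed W[0, 0] = 1 intercept component
        Vinv = np.linalg.inv(working_cov_z(mu[i], R.R, Y.family, phi))
        A += Mi.T @ Vinv @ Mi
        rhs += Mi.T @ Vinv @ (z[i] - offset)
    return np.linalg.solve(A + lam_G * np.eye(design.T), rhs)
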