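"""Doubly ridge-penalized GEE estimation of the hierarchical pathway model.

The model links rare-variant gene burdens to clustered phenotypes through
latent pathway components: each pathway component is a weighted sum of its
gene burdens (weights ``W``, ridge penalty ``lambda_G``), and the component
scores predict the ``Q`` phenotypes marginally through coefficients ``B``
(ridge penalty ``lambda_P``) under a working correlation ``R(alpha)``:

    g(mu_iq) = eta_iq = beta_0q + sum_k f_ik beta_kq,   f_ik = sum_t x_ikt w_tk

Estimation alternates two closed-form penalized generalized-least-squares
solves — coefficients ``B`` for fixed weights, then the free weights ``w_*``
for fixed ``B`` — followed by moment updates of the working correlation and
dispersion from Pearson residuals, until the parameters stabilize. Binary
phenotypes use the standard GEE working-response linearization
``z = eta + (y - mu) g'(mu)`` in both solves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .collapse import CollapsedDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteredPhenotypes",
    "WeightMatrix",
    "CoefficientMatrix",
    "WorkingCorrelation",
    "PenaltyConfig",
    "FitResult",
    "component_scores",
    "working_covariance",
    "update_B",
    "update_W",
    "pearson_residuals",
    "estimate_dispersion",
    "estimate_alpha",
    "fit",
]

_EPS_MU = 1e-8
_STRUCTURES = ("independence", "exchangeable", "ar1", "unstructured")


@dataclass
class ClusteredPhenotypes:
    """``N x Q`` complete-case response matrix with its exponential-family spec.

    ``family`` is ``"gaussian"`` (identity link, variance function 1) or
    ``"binomial"`` (logit link, variance function ``mu (1 - mu)``). Missing
    entries are not allowed: clusters must be complete.
    """

    Y: np.ndarray
    family: str = "gaussian"
    phenotype_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unsupported family {self.family!r}")
        if np.isnan(self.Y).any():
            raise ValueError("phenotypes must be complete cases (no missing entries)")
        if self.family == "binomial" and not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("binomial phenotypes must be coded {0, 1}")
        if self.phenotype_names is None:
            self.phenotype_names = [f"y{q + 1}" for q in range(self.Y.shape[1])]

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def Q(self) -> int:
        return self.Y.shape[1]


@dataclass
class WeightMatrix:
    """Block-sparse ``(T+1) x (K+1)`` component-weight matrix.

    ``W[0, 0]`` is fixed at 1 (intercept component); column ``k+1`` is non-zero
    only at the rows of pathway ``k``'s genes. ``pathway_of_col`` gives the
    0-based pathway index of each non-intercept design column.
    """

    w_star: np.ndarray
    pathway_of_col: np.ndarray
    K: int

    @property
    def T(self) -> int:
        return self.w_star.shape[0]

    @property
    def full(self) -> np.ndarray:
        W = np.zeros((self.T + 1, self.K + 1))
        W[0, 0] = 1.0
        W[np.arange(1, self.T + 1), self.pathway_of_col + 1] = self.w_star
        return W

    def block(self, k: int) -> np.ndarray:
        return self.w_star[self.pathway_of_col == k]


@dataclass
class CoefficientMatrix:
    """``(K+1) x Q`` coefficient matrix: row 0 intercepts, row k pathway k."""

    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if not np.isfinite(self.B).all():
            raise ValueError("coefficients must be finite")


@dataclass
class WorkingCorrelation:
    """Working within-cluster correlation ``R(alpha)`` of the Q phenotypes."""

    structure: str
    Q: int
    alpha: np.ndarray = field(default_factory=lambda: np.array([]))
    R: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown correlation structure {self.structure!r}")
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.R is None:
            self.R = self._build()

    def _build(self) -> np.ndarray:
        q = self.Q
        if self.structure == "independence" or self.alpha.size == 0:
            return np.eye(q)
        if self.structure == "exchangeable":
            a = float(self.alpha[0])
            return (1.0 - a) * np.eye(q) + a * np.ones((q, q))
        if self.structure == "ar1":
            a = float(self.alpha[0])
            idx = np.arange(q)
            return a ** np.abs(idx[:, None] - idx[None, :])
        R = np.eye(q)
        iu = np.triu_indices(q, k=1)
        R[iu] = self.alpha
        R[(iu[1], iu[0])] = self.alpha
        return _nearest_pd_correlation(R)

    @classmethod
    def identity(cls, Q: int) -> "WorkingCorrelation":
        return cls(structure="independence", Q=Q)


@dataclass
class PenaltyConfig:
    """Ridge penalties: ``lambda_G`` on gene weights, ``lambda_P`` on coefficients."""

    lambda_G: float = 1.0
    lambda_P: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_G) and np.isfinite(self.lambda_P)):
            raise ValueError("penalties must be finite")
        if self.lambda_G < 0 or self.lambda_P < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class FitResult:
    W: WeightMatrix
    B: CoefficientMatrix
    F: np.ndarray
    correlation: WorkingCorrelation
    phi: float
    residuals: np.ndarray
    n_iter: int
    converged: bool
    objective_trace: list[float]
    pathway_order: list[str]
    block_index: list[tuple[str, str]]

    @property
    def pathway_coefficients(self) -> np.ndarray:
        """``K x Q`` pathway coefficients (intercept row excluded)."""
        return self.B.B[1:, :]


def _nearest_pd_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floor repair of a symmetric matrix, rescaled to unit diagonal."""
    R = 0.5 * (R + R.T)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() > floor:
        return R
    warnings.warn("working correlation estimate not positive definite; flooring eigenvalues")
    vals = np.clip(vals, floor, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _link_inverse(eta: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        return eta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _variance_function(mu: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        return np.ones_like(mu)
    mu = np.clip(mu, _EPS_MU, 1.0 - _EPS_MU)
    return mu * (1.0 - mu)


def _working_response(eta: np.ndarray, mu: np.ndarray, Y: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        return Y
    nu = _variance_function(mu, family)
    return eta + (Y - mu) / nu  # g'(mu) = 1/(mu(1-mu)) for logit


def component_scores(design: CollapsedDesign, W: WeightMatrix) -> np.ndarray:
    """``N x (K+1)`` component-score matrix ``F = X W`` (column 0 all ones).

    Exploits the block sparsity of ``W``: each pathway score is the product
    of its own contiguous burden-column slice with its weight block.
    """
    if design.T != W.T:
        raise ValueError(f"design has T={design.T} burden columns but W has T={W.T}")
    kcol = W.pathway_of_col
    if np.any(np.diff(kcol) < 0):  # not pathway-major: fall back to dense product
        return design.X @ W.full
    Xg = design.X[:, 1:]
    F = np.empty((Xg.shape[0], W.K + 1))
    F[:, 0] = design.X[:, 0]
    starts = np.searchsorted(kcol, np.arange(W.K))
    stops = np.searchsorted(kcol, np.arange(W.K), side="right")
    for k in range(W.K):
        sl = slice(starts[k], stops[k])
        F[:, k + 1] = Xg[:, sl] @ W.w_star[sl]
    return F


def working_covariance(
    mu_i: np.ndarray, R: WorkingCorrelation, family: str, phi: float = 1.0
) -> np.ndarray:
    """Working covariance ``Sigma_i = phi A^{1/2} R A^{1/2}`` for one cluster."""
    mu_i = np.asarray(mu_i, dtype=float)
    if family == "binomial" and (np.any(mu_i <= 0) or np.any(mu_i >= 1)):
        warnings.warn("binomial means at the boundary; clamping to (eps, 1-eps)")
        mu_i = np.clip(mu_i, _EPS_MU, 1.0 - _EPS_MU)
    a_half = np.sqrt(_variance_function(mu_i, family))
    return phi * (np.outer(a_half, a_half) * R.R)


def pearson_residuals(Y: np.ndarray, mu: np.ndarray, family: str) -> np.ndarray:
    """``r = (y - mu) / sqrt(nu(mu))`` elementwise."""
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (Y - mu) / np.sqrt(_variance_function(mu, family))


def estimate_dispersion(residuals: np.ndarray, K: int, T_ks: list[int]) -> float:
    """Method-of-moments dispersion: sum of squared Pearson residuals over
    ``NQ - (K + sum_k T_k)`` degrees of freedom."""
    n, q = residuals.shape
    df = n * q - (K + int(sum(T_ks)))
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df}); model too large for N*Q")
    return float(np.sum(residuals**2) / df)


def estimate_alpha(residuals: np.ndarray, phi: float, structure: str) -> WorkingCorrelation:
    """Moment estimation of the working correlation from Pearson residuals."""
    r = np.asarray(residuals, dtype=float)
    n, q = r.shape
    if structure == "independence" or q == 1:
        return WorkingCorrelation(structure="independence", Q=q)
    if structure == "exchangeable":
        s1 = r.sum(axis=1)
        cross = 0.5 * (s1**2 - (r**2).sum(axis=1))  # sum over j<k of r_ij r_ik
        n_pairs = q * (q - 1) / 2
        a = float(cross.mean() / (n_pairs * phi))
        a = float(np.clip(a, -1.0 / (q - 1) + 1e-6, 1.0 - 1e-6))
        return WorkingCorrelation(structure="exchangeable", Q=q, alpha=np.array([a]))
    if structure == "ar1":
        a = float((r[:, :-1] * r[:, 1:]).mean() / phi)
        a = float(np.clip(a, -1.0 + 1e-6, 1.0 - 1e-6))
        return WorkingCorrelation(structure="ar1", Q=q, alpha=np.array([a]))
    # unstructured
    S = r.T @ r / (n * phi)
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, -1.0 + 1e-6, 1.0 - 1e-6)
    np.fill_diagonal(S, 1.0)
    R = _nearest_pd_correlation(S)
    iu = np.triu_indices(q, k=1)
    return WorkingCorrelation(structure="unstructured", Q=q, alpha=R[iu], R=R)


def _sigma_inverse_factors(
    mu: np.ndarray, R: WorkingCorrelation, family: str, phi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(s, Rinv)`` such that ``Sigma_i^{-1} = (s_i s_i' * Rinv)``
    with ``s_iq = nu(mu_iq)^{-1/2} / sqrt(phi)`` (covariance of the response)."""
    s = 1.0 / np.sqrt(_variance_function(mu, family))
    Rinv = np.linalg.inv(R.R)
    return s / np.sqrt(phi), Rinv


def _working_weight_factors(
    mu: np.ndarray, R: WorkingCorrelation, family: str, phi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse covariance factors for the eta-scale working response ``z``.

    ``var(z_i) ~ G Sigma_i G`` with ``G = diag(g'(mu))``; for the canonical
    logit link ``G = A^{-1}`` so the weight is ``A^{1/2} R^{-1} A^{1/2}/phi``
    — i.e. ``s_iq = nu(mu_iq)^{1/2}``. For the gaussian identity link this
    coincides with ``Sigma_i^{-1}``, the weighting the continuous-response
    updates are written with, and the resulting fixed point solves the GEE
    score equation ``sum_i D_i' Sigma_i^{-1} (y_i - mu_i) = penalty gradient``.
    """
    if family == "gaussian":
        s = np.ones_like(mu)
    else:
        s = np.sqrt(_variance_function(mu, family))
    Rinv = np.linalg.inv(R.R)
    return s / np.sqrt(phi), Rinv


def update_B(
    design: CollapsedDesign,
    W: WeightMatrix,
    B: CoefficientMatrix,
    Y: ClusteredPhenotypes,
    R: WorkingCorrelation,
    phi: float,
    lambda_P: float,
    penalize_intercept: bool = False,
) -> CoefficientMatrix:
    """Closed-form ridge-GLS update of the pathway coefficients for fixed weights.

    Solves ``(sum_i Q_i' V_i^{-1} Q_i + lambda_P P) b = sum_i Q_i' V_i^{-1} z_i``
    with ``Q_i = f_i' (x) I_Q`` and ``b`` stacking the rows of ``B`` (one
    ``Q``-block per component), where ``V_i`` is the working covariance of the
    eta-scale response ``z`` (equal to ``Sigma_i`` for gaussian responses; see
    :func:`_working_weight_factors`). For binary phenotypes ``z`` is the
    working response from the current ``(W, B)``; the intercept row is
    unpenalized by default.
    """
    F = component_scores(design, W)
    eta = F @ B.B
    mu = _link_inverse(eta, Y.family)
    z = _working_response(eta, mu, Y.Y, Y.family)
    s, Rinv = _working_weight_factors(mu, R, Y.family, phi)

    q = Y.Q
    kp1 = F.shape[1]
    G2 = (F[:, :, None] * s[:, None, :]).reshape(len(F), kp1 * q)  # N x (K+1)Q
    H = (G2.T @ G2).reshape(kp1, q, kp1, q) * Rinv[None, :, None, :]
    H = H.reshape(kp1 * q, kp1 * q)
    u = (s * z) @ Rinv
    rhs = (F.T @ (s * u)).reshape(kp1 * q)

    pen = np.full(kp1 * q, lambda_P)
    if not penalize_intercept:
        pen[:q] = 0.0
    try:
        b = np.linalg.solve(H + np.diag(pen), rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular coefficient system; components may be collinear — set lambda_P > 0"
        ) from exc
    return CoefficientMatrix(B=b.reshape(kp1, q))


def update_W(
    design: CollapsedDesign,
    W: WeightMatrix,
    B: CoefficientMatrix,
    Y: ClusteredPhenotypes,
    R: WorkingCorrelation,
    phi: float,
    lambda_G: float,
) -> WeightMatrix:
    """Closed-form ridge-GLS update of the free gene weights for fixed ``B``.

    The design of the linearized system is ``M_i = x_i' (x) B'`` restricted to
    the structurally non-zero weight positions; the intercept contribution
    ``beta_0`` enters as a fixed offset. Structural zeros of ``W`` are
    preserved exactly by construction.
    """
    F = component_scores(design, W)
    eta = F @ B.B
    mu = _link_inverse(eta, Y.family)
    z = _working_response(eta, mu, Y.Y, Y.family)
    s, Rinv = _working_weight_factors(mu, R, Y.family, phi)

    Xg = design.X[:, 1:]  # N x T burden columns
    kcol = W.pathway_of_col
    B1 = B.B[1:, :]  # K x Q pathway rows
    # E[i, k, q] = B1[k, q] * s[i, q]
    E = B1[None, :, :] * s[:, None, :]
    n, K_, q_ = E.shape
    ERi = (E.reshape(n * K_, q_) @ Rinv).reshape(n, K_, q_)
    C = np.matmul(ERi, E.transpose(0, 2, 1))  # N x K x K

    # H[t, u] = sum_i x_it x_iu C_i[k(t), k(u)], assembled per destination block;
    # columns are pathway-major so every block is a contiguous slice
    T = W.T
    H = np.empty((T, T))
    n = Xg.shape[0]
    starts = np.searchsorted(kcol, np.arange(W.K))
    stops = np.searchsorted(kcol, np.arange(W.K), side="right")
    scaled = np.empty((n, T))
    for l in range(W.K):
        sl = slice(starts[l], stops[l])
        if sl.start == sl.stop:
            continue
        for k in range(W.K):
            sk = slice(starts[k], stops[k])
            np.multiply(Xg[:, sk], C[:, k, l][:, None], out=scaled[:, sk])
        H[:, sl] = scaled.T @ Xg[:, sl]
    resid = z - B.B[0, :][None, :]  # offset: intercept component is fixed
    u = (s * resid) @ Rinv
    d = np.matmul(E, u[:, :, None])[:, :, 0]  # E already carries one factor of s
    rhs = (Xg * d[:, kcol]).sum(axis=0)

    try:
        w_star = np.linalg.solve(H + lambda_G * np.eye(T), rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular weight system; gene burdens may be collinear — set lambda_G > 0"
        ) from exc
    return WeightMatrix(w_star=w_star, pathway_of_col=kcol, K=W.K)


def _quasi_deviance_total(Y: np.ndarray, mu: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.sum((Y - mu) ** 2))
    mu = np.clip(mu, _EPS_MU, 1.0 - _EPS_MU)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
        term0 = np.where(Y < 1, (1.0 - Y) * np.log((1.0 - Y) / (1.0 - mu)), 0.0)
    return float(2.0 * np.sum(term1 + term0))


def _gauss_newton_step(
    design: CollapsedDesign,
    W: WeightMatrix,
    B: CoefficientMatrix,
    Y: ClusteredPhenotypes,
    R: WorkingCorrelation,
    phi: float,
    penalties: "PenaltyConfig",
    penalize_intercept: bool = False,
) -> tuple[CoefficientMatrix, WeightMatrix]:
    """One ridge-penalized Gauss-Newton step on ``(b, w_*)`` jointly.

    Linearizes the bilinear predictor in both parameter blocks at once and
    solves the coupled normal equations. The stationary point coincides with
    that of the alternating blockwise solves (both zero the same penalized
    GEE score), so this serves as an endgame accelerator once the
    alternation is close: its local convergence is superlinear where the
    blockwise sweep is linear.
    """
    F = component_scores(design, W)
    eta = F @ B.B
    mu = _link_inverse(eta, Y.family)
    z = _working_response(eta, mu, Y.Y, Y.family)
    s, Rinv = _working_weight_factors(mu, R, Y.family, phi)
    q = Y.Q
    kp1 = F.shape[1]
    T = W.T
    kcol = W.pathway_of_col
    Xg = design.X[:, 1:]
    B1 = B.B[1:, :]

    G = F[:, :, None] * s[:, None, :]
    G2 = G.reshape(len(F), kp1 * q)
    H_bb = ((G2.T @ G2).reshape(kp1, q, kp1, q) * Rinv[None, :, None, :]).reshape(
        kp1 * q, kp1 * q
    )
    Es = B1[None, :, :] * s[:, None, :]
    n_, K_, q_ = Es.shape
    A2 = (Es.reshape(n_ * K_, q_) @ Rinv).reshape(n_, K_, q_)
    C = np.matmul(A2, Es.transpose(0, 2, 1))
    H_ww = np.empty((T, T))
    starts = np.searchsorted(kcol, np.arange(W.K))
    stops = np.searchsorted(kcol, np.arange(W.K), side="right")
    scaled = np.empty_like(Xg)
    for l in range(W.K):
        sl = slice(starts[l], stops[l])
        if sl.start == sl.stop:
            continue
        for k in range(W.K):
            sk = slice(starts[k], stops[k])
            np.multiply(Xg[:, sk], C[:, k, l][:, None], out=scaled[:, sk])
        H_ww[:, sl] = scaled.T @ Xg[:, sl]
    P2 = Xg[:, :, None] * A2[:, kcol, :]
    H_bw = np.empty((kp1, q, T))
    for qi in range(q):
        H_bw[:, qi, :] = G[:, :, qi].T @ P2[:, :, qi]
    H_bw = H_bw.reshape(kp1 * q, T)

    r = z - eta
    u = (s * r) @ Rinv
    g_b = (F.T @ (s * u)).reshape(kp1 * q)
    d = np.matmul(Es, u[:, :, None])[:, :, 0]  # Es carries one s factor
    g_w = (Xg * d[:, kcol]).sum(axis=0)

    # bilinear cross term of the score Jacobian: d(J_b' W r)/dw has a
    # residual-weighted part because the b-design itself depends on w
    V = Xg.T @ (s * u)
    Kx = np.zeros((kp1, q, T))
    Kx[kcol + 1, :, np.arange(T)] = V
    Kx = Kx.reshape(kp1 * q, T)

    pen_b = np.full(kp1 * q, penalties.lambda_P)
    if not penalize_intercept:
        pen_b[:q] = 0.0
    b_old = B.B.reshape(kp1 * q)
    rhs = np.concatenate([g_b - pen_b * b_old, g_w - penalties.lambda_G * W.w_star])
    Hfull = np.block(
        [[H_bb + np.diag(pen_b), H_bw - Kx], [(H_bw - Kx).T, H_ww + penalties.lambda_G * np.eye(T)]]
    )
    delta = np.linalg.solve(Hfull, rhs)
    B_new = CoefficientMatrix(B=(b_old + delta[: kp1 * q]).reshape(kp1, q))
    W_new = WeightMatrix(
        w_star=W.w_star + delta[kp1 * q :], pathway_of_col=kcol, K=W.K
    )
    return B_new, W_new


def _pearson_merit(
    design: CollapsedDesign,
    W: WeightMatrix,
    B: CoefficientMatrix,
    Y: ClusteredPhenotypes,
    R: WorkingCorrelation,
    phi: float,
    penalties: "PenaltyConfig",
) -> float:
    """Penalized generalized Pearson chi-square used as a line-search merit.

    ``sum_i (y_i - mu_i)' Sigma_i^{-1} (y_i - mu_i)`` plus the two ridge
    terms. For gaussian responses this is exactly the penalized GLS
    criterion that the closed-form updates minimize blockwise; for binomial
    responses it diverges when means saturate, which is what the damping
    guards against.
    """
    F = component_scores(design, W)
    mu = _link_inverse(F @ B.B, Y.family)
    s, Rinv = _sigma_inverse_factors(mu, R, Y.family, phi)
    e = (Y.Y - mu) * s
    chi2 = float(((e @ Rinv) * e).sum())
    return (
        chi2
        + penalties.lambda_P * float(np.sum(B.B[1:, :] ** 2))
        + penalties.lambda_G * float(np.sum(W.w_star**2))
    )


def _merit_from_mu(
    W: WeightMatrix,
    B: CoefficientMatrix,
    Y: ClusteredPhenotypes,
    mu: np.ndarray,
    R: WorkingCorrelation,
    phi: float,
    penalties: "PenaltyConfig",
) -> float:
    """As :func:`_pearson_merit` but reusing already-computed fitted means."""
    s, Rinv = _sigma_inverse_factors(mu, R, Y.family, phi)
    e = (Y.Y - mu) * s
    chi2 = float(((e @ Rinv) * e).sum())
    return (
        chi2
        + penalties.lambda_P * float(np.sum(B.B[1:, :] ** 2))
        + penalties.lambda_G * float(np.sum(W.w_star**2))
    )


def _rebalance_scale(
    W: WeightMatrix, B: CoefficientMatrix, lambda_G: float, lambda_P: float
) -> tuple[WeightMatrix, CoefficientMatrix]:
    """Move each pathway block to its penalty-optimal point on the scale-invariance ray.

    The linear predictor only identifies the products ``w_tk * beta_kq``;
    multiplying a block's weights by ``c`` and dividing its coefficient row
    by ``c`` leaves eta unchanged while the ridge terms vary. The optimal
    ``c`` has ``c^4 = lambda_P ||beta_k||^2 / (lambda_G ||w_k||^2)``.
    Jumping there each iteration removes the flat valley that otherwise
    slows the alternation to a crawl.
    """
    if lambda_G <= 0 or lambda_P <= 0:
        return W, B
    w = W.w_star.copy()
    Bm = B.B.copy()
    for k in range(W.K):
        mask = W.pathway_of_col == k
        nw2 = float(np.sum(w[mask] ** 2))
        nb2 = float(np.sum(Bm[k + 1, :] ** 2))
        if nw2 <= 0 or nb2 <= 0:
            continue
        c = (lambda_P * nb2 / (lambda_G * nw2)) ** 0.25
        w[mask] *= c
        Bm[k + 1, :] /= c
    return WeightMatrix(w_star=w, pathway_of_col=W.pathway_of_col, K=W.K), CoefficientMatrix(B=Bm)


def _apply_sign_convention(W: WeightMatrix, B: CoefficientMatrix) -> tuple[WeightMatrix, CoefficientMatrix]:
    """Flip each pathway's (weights, coefficient row) jointly so the
    largest-magnitude weight in the block is positive; eta is unchanged."""
    w = W.w_star.copy()
    Bm = B.B.copy()
    for k in range(W.K):
        mask = W.pathway_of_col == k
        if not mask.any():
            continue
        blk = w[mask]
        if blk[np.argmax(np.abs(blk))] < 0:
            w[mask] = -blk
            Bm[k + 1, :] = -Bm[k + 1, :]
    return WeightMatrix(w_star=w, pathway_of_col=W.pathway_of_col, K=W.K), CoefficientMatrix(B=Bm)


def fit(
    design: CollapsedDesign,
    Y: ClusteredPhenotypes,
    penalties: PenaltyConfig | None = None,
    structure: str = "exchangeable",
    max_iter: int = 200,
    tol: float = 1e-5,
    estimate_phi: bool | None = None,
    standardize_components: bool = False,
    penalize_intercept: bool = False,
    init: "FitResult | None" = None,
) -> FitResult:
    """Fit the penalized hierarchical GEE model by alternating updates.

    Each iteration updates ``B`` (coefficients), then the free weights
    ``w_*``, then the working correlation and dispersion from Pearson
    residuals, until the largest absolute parameter change falls below
    ``tol``. The dispersion is estimated for gaussian phenotypes and fixed at
    1 for binary phenotypes unless ``estimate_phi`` overrides it. Returns the
    best iterate with ``converged=False`` (and a warning) when ``max_iter``
    is exhausted.
    """
    penalties = penalties or PenaltyConfig()
    if estimate_phi is None:
        estimate_phi = Y.family == "gaussian"
    if design.N != Y.N:
        raise ValueError("design and phenotypes disagree on the number of samples")

    kcol = design.pathway_of_column()
    K = design.K
    T_ks = design.T_k
    # deterministic scale-consistent start: unit-norm component per block
    w0 = np.empty(design.T)
    for k in range(K):
        mask = kcol == k
        w0[mask] = 1.0 / np.sqrt(mask.sum())
    W = WeightMatrix(w_star=w0, pathway_of_col=kcol, K=K)

    ybar = Y.Y.mean(axis=0)
    if Y.family == "binomial":
        p = np.clip(ybar, _EPS_MU, 1 - _EPS_MU)
        intercept0 = np.log(p / (1 - p))
    else:
        intercept0 = ybar
    B0 = np.zeros((K + 1, Y.Q))
    B0[0, :] = intercept0
    B = CoefficientMatrix(B=B0)

    R = WorkingCorrelation.identity(Y.Q)
    phi = 1.0
    if init is not None:
        # warm start from a previous fit on the same design (e.g. across
        # permutations); the fixed point does not depend on the start
        W = WeightMatrix(w_star=init.W.w_star.copy(), pathway_of_col=kcol, K=K)
        B = CoefficientMatrix(B=init.B.B.copy())
        R = init.correlation
        phi = float(init.phi)
    trace: list[float] = []
    converged = False
    n_iter = 0

    delta_prev: np.ndarray | None = None
    merit_best = merit_carry = _pearson_merit(design, W, B, Y, R, phi, penalties)
    for n_iter in range(1, max_iter + 1):
        b_old = B.B.copy()
        w_old = W.w_star.copy()

        merit_old = merit_carry
        merit_best = min(merit_best, merit_old)
        merit_cap = 1.2 * merit_best + 1.0

        def _guarded_step(B_cand: CoefficientMatrix, W_cand: WeightMatrix):
            # full step when possible; the GEE fixed point need not minimize
            # the Pearson merit exactly, so a modest band above the best merit
            # seen is allowed, but steps escaping that band (saturating
            # binomial means, oscillation) are halved back
            step = 1.0
            while True:
                B_try = CoefficientMatrix(B=b_old + step * (B_cand.B - b_old))
                W_try = WeightMatrix(
                    w_star=w_old + step * (W_cand.w_star - w_old),
                    pathway_of_col=W.pathway_of_col,
                    K=W.K,
                )
                merit_try = _pearson_merit(design, W_try, B_try, Y, R, phi, penalties)
                if np.isfinite(merit_try) and merit_try <= max(merit_cap, merit_old):
                    return B_try, W_try, step, True
                if step <= 1.0 / 1024:
                    return B_try, W_try, step, False
                step /= 2.0

        near_solution = delta_prev is not None and float(np.abs(delta_prev).max()) < 3e-2
        accepted = False
        if near_solution:
            try:
                B_cand, W_cand = _gauss_newton_step(
                    design, W, B, Y, R, phi, penalties, penalize_intercept
                )
                B_try, W_try, step, accepted = _guarded_step(B_cand, W_cand)
            except np.linalg.LinAlgError:
                near_solution = False
        if not near_solution or not accepted:
            # blockwise alternating sweep — the workhorse far from the
            # solution and the fallback when a joint Newton step is rejected
            near_solution = False
            B_cand = update_B(design, W, B, Y, R, phi, penalties.lambda_P, penalize_intercept)
            W_cand = update_W(design, W, B_cand, Y, R, phi, penalties.lambda_G)
            B_try, W_try, step, _ = _guarded_step(B_cand, W_cand)
        B, W = B_try, W_try
        if not near_solution:
            # the rebalance accelerates the blockwise sweeps but would fight
            # the joint Newton step, whose system already handles the valley
            W, B = _rebalance_scale(W, B, penalties.lambda_G, penalties.lambda_P)

        delta_vec = np.concatenate([(B.B - b_old).ravel(), W.w_star - w_old])
        # Aitken-style extrapolation along the dominant slow geometric mode
        if delta_prev is not None and n_iter % 5 == 0 and step == 1.0 and not near_solution:
            den = float(delta_prev @ delta_prev)
            rate = float(delta_vec @ delta_prev) / den if den > 0 else 0.0
            if 0.5 < rate < 0.999:
                fac = rate / (1.0 - rate)
                B_x = CoefficientMatrix(
                    B=B.B + fac * delta_vec[: B.B.size].reshape(B.B.shape)
                )
                W_x = WeightMatrix(
                    w_star=W.w_star + fac * delta_vec[B.B.size :],
                    pathway_of_col=W.pathway_of_col,
                    K=W.K,
                )
                merit_x = _pearson_merit(design, W_x, B_x, Y, R, phi, penalties)
                if np.isfinite(merit_x) and merit_x <= max(merit_cap, merit_old):
                    B, W = B_x, W_x
                    W, B = _rebalance_scale(W, B, penalties.lambda_G, penalties.lambda_P)
        delta_prev = delta_vec
        if standardize_components:
            W = _rescale_components(design, W)

        F = component_scores(design, W)
        eta = F @ B.B
        mu = _link_inverse(eta, Y.family)
        r = pearson_residuals(Y.Y, mu, Y.family)
        if estimate_phi:
            # floor keeps the weighting finite when the fit is exact
            phi = max(estimate_dispersion(r, K, T_ks), 1e-10)
        R = estimate_alpha(r, phi, structure)
        merit_carry = _merit_from_mu(W, B, Y, mu, R, phi, penalties)

        obj = (
            _quasi_deviance_total(Y.Y, mu, Y.family)
            + penalties.lambda_P * float(np.sum(B.B[1:, :] ** 2))
            + penalties.lambda_G * float(np.sum(W.w_star**2))
        )
        trace.append(obj)
        delta = max(
            float(np.max(np.abs(B.B - b_old))), float(np.max(np.abs(W.w_star - w_old)))
        )
        logger.info("iter %d: max parameter change %.3e, objective %.6g", n_iter, delta, obj)
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"did not converge in {max_iter} iterations; returning last iterate")

    W, B = _apply_sign_convention(W, B)
    F = component_scores(design, W)
    mu = _link_inverse(F @ B.B, Y.family)
    r = pearson_residuals(Y.Y, mu, Y.family)
    return FitResult(
        W=W,
        B=B,
        F=F,
        correlation=R,
        phi=phi,
        residuals=r,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
        pathway_order=list(design.pathway_order),
        block_index=list(design.block_index),
    )


def _rescale_components(design: CollapsedDesign, W: WeightMatrix) -> WeightMatrix:
    """Optionally rescale each weight block so its component has unit variance."""
    F = design.X[:, 1:] @ _free_to_cols(W)
    sd = F.std(axis=0, ddof=0)
    w = W.w_star.copy()
    for k in range(W.K):
        if sd[k] > 0:
            w[W.pathway_of_col == k] /= sd[k]
    return WeightMatrix(w_star=w, pathway_of_col=W.pathway_of_col, K=W.K)


def _free_to_cols(W: WeightMatrix) -> np.ndarray:
    M = np.zeros((W.T, W.K))
    M[np.arange(W.T), W.pathway_of_col] = W.w_star
    return M
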