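"""Permutation-based significance testing of pathway and gene effects.

The joint effect of pathway ``k`` on all ``Q`` phenotypes is tested with a
Wald-type statistic ``T = beta_k' cov^{-1}(beta_k) beta_k``. The null
distribution is built by permuting whole phenotype rows across individuals
(which preserves the within-cluster correlation) and refitting the full
model with identical penalties; by default the coefficient covariance is the
sample covariance of the permuted coefficients (the cheap "indirect" route),
with a penalized-GEE sandwich estimator available as an alternative.
Benjamini-Hochberg q-values and Westfall-Young max-T adjusted p-values are
provided for multiplicity control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapse import CollapsedDesign
from .gee_core import (
    ClusteredPhenotypes,
    FitResult,
    PenaltyConfig,
    _variance_function,
    component_scores,
    fit,
)

__all__ = [
    "PathwayTestResult",
    "PermutationNull",
    "SandwichParts",
    "wald_statistic",
    "permutation_covariance",
    "sandwich_covariance",
    "permutation_test",
    "PermutationTestOutcome",
    "bh_fdr",
    "westfall_young",
]


@dataclass
class PathwayTestResult:
    pathway_id: str
    T_obs: float
    p_value: float
    q_value: float
    wy_adjusted_p: float
    beta_hat: np.ndarray
    cov_beta: np.ndarray


@dataclass
class PermutationNull:
    """Null draws of the model parameters from phenotype-row permutations."""

    n_perm: int
    seed: int
    null_betas: np.ndarray  # n_perm x K x Q
    null_weights: np.ndarray  # n_perm x T
    null_T: np.ndarray  # n_perm x K


@dataclass
class SandwichParts:
    H: np.ndarray
    E: np.ndarray
    M: np.ndarray
    cov: np.ndarray


@dataclass
class PermutationTestOutcome:
    pathway_results: list[PathwayTestResult]
    gene_table: pd.DataFrame
    null: PermutationNull
    fit_obs: FitResult

    @property
    def pathway_table(self) -> pd.DataFrame:
        rows = []
        for r in self.pathway_results:
            row = {
                "pathway": r.pathway_id,
                "T": r.T_obs,
                "p": r.p_value,
                "q": r.q_value,
                "wy_p": r.wy_adjusted_p,
            }
            for q, b in enumerate(r.beta_hat):
                row[f"beta_{q + 1}"] = b
            rows.append(row)
        return pd.DataFrame(rows)


def wald_statistic(beta_k: np.ndarray, cov_beta: np.ndarray) -> float:
    """Quadratic form ``beta' cov^{-1} beta`` testing all Q coefficients jointly.

    Falls back to the Moore-Penrose pseudo-inverse (with a warning) when the
    covariance is singular, e.g. from degenerate permutation draws.
    """
    beta_k = np.atleast_1d(np.asarray(beta_k, dtype=float))
    cov_beta = np.atleast_2d(np.asarray(cov_beta, dtype=float))
    try:
        sol = np.linalg.solve(cov_beta, beta_k)
    except np.linalg.LinAlgError:
        warnings.warn("singular coefficient covariance; using pseudo-inverse")
        sol = np.linalg.pinv(cov_beta) @ beta_k
    return float(beta_k @ sol)


def permutation_covariance(null_betas_k: np.ndarray) -> np.ndarray:
    """Sample covariance (denominator ``n_perm - 1``) of permuted coefficients.

    ``null_betas_k`` is ``n_perm x Q`` for a single pathway.
    """
    null_betas_k = np.atleast_2d(np.asarray(null_betas_k, dtype=float))
    n_perm, q = null_betas_k.shape
    if n_perm < q + 2:
        raise ValueError(f"need at least Q+2={q + 2} permutations, got {n_perm}")
    centered = null_betas_k - null_betas_k.mean(axis=0)
    return centered.T @ centered / (n_perm - 1)


def sandwich_covariance(
    design: CollapsedDesign,
    Y: ClusteredPhenotypes,
    fit_result: FitResult,
    lambda_P: float = 0.0,
    penalize_intercept: bool = False,
) -> SandwichParts:
    """Penalized-GEE sandwich covariance of the stacked coefficient vector.

    Bread: ``H = sum_i Q_i' A_i^{1/2} R^{-1} A_i^{1/2} Q_i`` plus the ridge
    contribution ``E`` (zero on the unpenalized intercept block); meat:
    ``M = sum_i Q_i' A_i^{1/2} R^{-1} e_i e_i' R^{-1} A_i^{1/2} Q_i`` with the
    standardized residual ``e_i = A_i^{-1/2}(y_i - mu_i)``. The coefficient
    vector stacks the rows of ``B`` (one Q-block per component), matching the
    estimation order.
    """
    F = component_scores(design, fit_result.W)
    eta = F @ fit_result.B.B
    if Y.family == "gaussian":
        mu = eta
    else:
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    a_half = np.sqrt(_variance_function(mu, Y.family))
    Rinv = np.linalg.inv(fit_result.correlation.R)
    q = Y.Q
    kp1 = F.shape[1]

    G = F[:, :, None] * a_half[:, None, :]  # rows of A^{1/2} Q_i per component
    H = (np.einsum("iaq,ibr->aqbr", G, G, optimize=True) * Rinv[None, :, None, :]).reshape(
        kp1 * q, kp1 * q
    )
    e = (Y.Y - mu) / a_half
    v = e @ Rinv  # R^{-1} e_i
    # per-sample score over the stacked (component, phenotype) index
    S = (G * v[:, None, :]).reshape(len(e), kp1 * q)
    M = S.T @ S
    pen = np.full(kp1 * q, lambda_P)
    if not penalize_intercept:
        pen[:q] = 0.0
    E = np.diag(pen)
    bread = H + E
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular bread matrix in sandwich estimator; increase lambda_P"
        ) from exc
    cov = bread_inv @ M @ bread_inv
    cov = 0.5 * (cov + cov.T)
    return SandwichParts(H=H, E=E, M=M, cov=cov)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def westfall_young(null_T: np.ndarray, T_obs: np.ndarray) -> np.ndarray:
    """Single-step max-T adjusted p-values from joint permutation statistics.

    ``adj_p_k = (1 + #{perm : max_k' null_T >= T_obs_k}) / (n_perm + 1)``;
    dominates the raw permutation p-value and reduces to it when K = 1.
    """
    null_T = np.atleast_2d(np.asarray(null_T, dtype=float))
    T_obs = np.atleast_1d(np.asarray(T_obs, dtype=float))
    n_perm = null_T.shape[0]
    max_null = null_T.max(axis=1)
    exceed = (max_null[:, None] >= T_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def permutation_test(
    design: CollapsedDesign,
    Y: ClusteredPhenotypes,
    penalties: PenaltyConfig | None = None,
    structure: str = "exchangeable",
    n_perm: int = 1000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    covariance: str = "permutation",
) -> PermutationTestOutcome:
    """Permutation test of the joint pathway effects (and gene weights).

    Entire phenotype rows are permuted across individuals, preserving the
    clustered correlation under the null; every permutation refits the full
    model with the same penalties and correlation structure. Pathway
    p-values use the add-one permutation formula
    ``p = (1 + #{null_T >= T_obs}) / (n_perm + 1)``; gene p-values are
    two-sided quantiles of each fitted weight against its permutation null.
    """
    penalties = penalties or PenaltyConfig()
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm < 1000:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is 1/{n_perm + 1}")

    fit_kwargs = dict(
        penalties=penalties, structure=structure, max_iter=max_iter, tol=tol
    )
    fit_obs = fit(design, Y, **fit_kwargs)
    K, Q, T = design.K, Y.Q, design.T
    beta_obs = fit_obs.pathway_coefficients  # K x Q
    w_obs = fit_obs.W.w_star

    rng = np.random.default_rng(seed)
    null_betas = np.empty((n_perm, K, Q))
    null_weights = np.empty((n_perm, T))
    n_failed = 0
    kept = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.N)
        Yp = ClusteredPhenotypes(Y=Y.Y[perm], family=Y.family, phenotype_names=Y.phenotype_names)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fp = fit(design, Yp, **fit_kwargs)
        except np.linalg.LinAlgError:
            n_failed += 1
            if n_failed > 0.05 * n_perm:
                raise RuntimeError(
                    f"{n_failed} permutation fits failed (> 5% of {n_perm}); "
                    "check penalties and data conditioning"
                )
            continue
        null_betas[kept] = fp.pathway_coefficients
        null_weights[kept] = fp.W.w_star
        kept += 1
    null_betas = null_betas[:kept]
    null_weights = null_weights[:kept]
    n_eff = kept

    covs = []
    T_obs = np.empty(K)
    null_T = np.empty((n_eff, K))
    for k in range(K):
        if covariance == "permutation":
            cov_k = permutation_covariance(null_betas[:, k, :])
        elif covariance == "sandwich":
            parts = sandwich_covariance(
                design, Y, fit_obs, lambda_P=penalties.lambda_P
            )
            block = slice((k + 1) * Q, (k + 2) * Q)
            cov_k = parts.cov[block, block]
        else:
            raise ValueError(f"unknown covariance method {covariance!r}")
        covs.append(cov_k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T_obs[k] = wald_statistic(beta_obs[k], cov_k)
        try:
            sol = np.linalg.solve(cov_k, null_betas[:, k, :].T)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(cov_k) @ null_betas[:, k, :].T
        null_T[:, k] = np.einsum("pq,qp->p", null_betas[:, k, :], sol)

    p_path = (1.0 + (null_T >= T_obs[None, :]).sum(axis=0)) / (n_eff + 1.0)
    q_path = bh_fdr(p_path)
    wy_path = westfall_young(null_T, T_obs)

    results = [
        PathwayTestResult(
            pathway_id=design.pathway_order[k],
            T_obs=float(T_obs[k]),
            p_value=float(p_path[k]),
            q_value=float(q_path[k]),
            wy_adjusted_p=float(wy_path[k]),
            beta_hat=beta_obs[k].copy(),
            cov_beta=covs[k],
        )
        for k in range(K)
    ]

    p_gene = (1.0 + (np.abs(null_weights) >= np.abs(w_obs)[None, :]).sum(axis=0)) / (
        n_eff + 1.0
    )
    gene_table = pd.DataFrame(
        {
            "gene": [g for _, g in design.block_index],
            "pathway": [pw for pw, _ in design.block_index],
            "weight": w_obs,
            "p": p_gene,
            "q": bh_fdr(p_gene),
        }
    )

    null = PermutationNull(
        n_perm=n_eff, seed=seed, null_betas=null_betas, null_weights=null_weights, null_T=null_T
    )
    return PermutationTestOutcome(
        pathway_results=results, gene_table=gene_table, null=null, fit_obs=fit_obs
    )
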