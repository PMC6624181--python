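"""Selection of the two ridge penalties by k-fold cross-validation.

The pair ``(lambda_G, lambda_P)`` is chosen on a two-dimensional grid by
minimizing the unpenalized predictive quasi-deviance accumulated over held-out
folds. Standardization of the burden columns is recomputed inside each
training fold and applied to the held-out fold, so no holdout information
leaks into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .collapse import CollapsedDesign
from .gee_core import ClusteredPhenotypes, PenaltyConfig, _link_inverse, fit

logger = logging.getLogger(__name__)

__all__ = ["CVGrid", "quasi_deviance", "cross_validate"]

_EPS = 1e-8


@dataclass
class CVGrid:
    """Candidate penalty values and the fold layout for cross-validation."""

    lambda_G_values: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0])
    lambda_P_values: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0])
    k_folds: int = 5
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_G_values or not self.lambda_P_values:
            raise ValueError("penalty grids must be non-empty")
        if any(l <= 0 for l in self.lambda_G_values + self.lambda_P_values):
            raise ValueError("grid penalties must be positive")
        if self.k_folds < 2:
            raise ValueError("need at least 2 folds")
        self.lambda_G_values = sorted(self.lambda_G_values)
        self.lambda_P_values = sorted(self.lambda_P_values)


def quasi_deviance(Y_holdout: np.ndarray, mu_pred: np.ndarray, family: str) -> float:
    """Unpenalized predictive quasi-deviance.

    Gaussian: residual sum of squares. Binomial:
    ``2 sum [y log(y/mu) + (1-y) log((1-y)/(1-mu))]`` with ``0 log 0 = 0``.
    """
    y = np.asarray(Y_holdout, dtype=float)
    mu = np.asarray(mu_pred, dtype=float)
    if family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t0 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t0))


def _fold_standardize(
    X_raw: np.ndarray, train: np.ndarray, holdout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize burden columns with training-fold statistics only.

    Returns (X_train, X_holdout, keep_mask over non-intercept columns); the
    training block satisfies diag(X'X) = N_train I on the kept columns.
    """
    burdens = X_raw[:, 1:]
    mean = burdens[train].mean(axis=0)
    centered_tr = burdens[train] - mean
    ss = np.einsum("ij,ij->j", centered_tr, centered_tr)
    keep = ss > 1e-12
    scale = np.sqrt(train.size / ss[keep])
    Xt = np.column_stack([np.ones(train.size), centered_tr[:, keep] * scale])
    centered_ho = (burdens[holdout] - mean)[:, keep] * scale
    Xh = np.column_stack([np.ones(holdout.size), centered_ho])
    return Xt, Xh, keep


def cross_validate(
    design: CollapsedDesign,
    Y: ClusteredPhenotypes,
    grid: CVGrid | None = None,
    structure: str = "exchangeable",
    max_iter: int = 200,
    tol: float = 1e-5,
) -> tuple[float, float, pd.DataFrame]:
    """Grid search for ``(lambda_G, lambda_P)`` by k-fold predictive quasi-deviance.

    Ties are broken toward the larger penalty pair (more regularization).
    Requires ``design.X_raw`` (kept by the collapsing step) so that each
    training fold can be re-standardized independently. Returns the selected
    pair and the full CV table.
    """
    grid = grid or CVGrid()
    if design.X_raw is None:
        raise ValueError("design must carry the raw burdens (X_raw) for fold-wise standardization")
    if design.N < grid.k_folds:
        raise ValueError("fewer samples than folds")

    kf = KFold(n_splits=grid.k_folds, shuffle=True, random_state=grid.fold_seed)
    folds = list(kf.split(np.arange(design.N)))

    rows = []
    for lg in grid.lambda_G_values:
        for lp in grid.lambda_P_values:
            total, valid = 0.0, True
            for train, holdout in folds:
                try:
                    Xt, Xh, keep = _fold_standardize(design.X_raw, train, holdout)
                    bi = [b for b, k in zip(design.block_index, keep) if k]
                    d_tr = CollapsedDesign(
                        X=Xt, block_index=bi, pathway_order=list(design.pathway_order)
                    )
                    Yt = ClusteredPhenotypes(
                        Y=Y.Y[train], family=Y.family, phenotype_names=Y.phenotype_names
                    )
                    res = fit(
                        d_tr,
                        Yt,
                        penalties=PenaltyConfig(lambda_G=lg, lambda_P=lp),
                        structure=structure,
                        max_iter=max_iter,
                        tol=tol,
                    )
                    mu_ho = _link_inverse(Xh @ res.W.full @ res.B.B, Y.family)
                    total += quasi_deviance(Y.Y[holdout], mu_ho, Y.family)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    logger.warning("CV cell (%g, %g) failed: %s", lg, lp, exc)
                    valid = False
                    break
            rows.append(
                {
                    "lambda_G": lg,
                    "lambda_P": lp,
                    "quasi_deviance": total if valid else np.nan,
                    "valid": valid,
                }
            )
    table = pd.DataFrame(rows)
    if not table["valid"].any():
        raise RuntimeError("all CV grid cells failed")
    ok = table[table["valid"]]
    best_qd = ok["quasi_deviance"].min()
    ties = ok[np.isclose(ok["quasi_deviance"], best_qd)]
    # prefer larger penalties among ties
    best = ties.sort_values(["lambda_G", "lambda_P"]).iloc[-1]
    return float(best["lambda_G"]), float(best["lambda_P"]), table
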