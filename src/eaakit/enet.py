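"""Elastic-net penalized logistic regression (glmnet-scale parameterization).

Minimises

    (1/n) Σ_i [ −y_i·η_i + log(1 + exp(η_i)) ]  +  λ·( α·‖β‖₁ + (1−α)/2·‖β‖₂² )

with η_i = β₀ + x_iᵀβ and an unpenalized intercept, by iteratively
reweighted least squares with an inner cyclic coordinate-descent loop and
the soft-threshold update — the same objective and (α, λ) scale glmnet
uses, so printed parameter pairs such as (0.05, 0.16) are directly
comparable across software.  Features are assumed pre-standardised (the
classifier pipeline scales them); no internal standardisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .types import ConfigError, ConvergenceError

_MIN_WEIGHT = 1e-5  # floor on IRLS weights, as in glmnet


@dataclass
class EnetFit:
    coef: np.ndarray
    intercept: float
    alpha: float
    lam: float
    n_iter: int
    converged: bool

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.decision(X), -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))


def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 500,
    strict: bool = True,
) -> EnetFit:
    """Fit the penalized logistic model.

    Parameters
    ----------
    alpha : mixing parameter in [0, 1] (1 = pure lasso, 0 = pure ridge).
    lam : penalty strength ≥ 0 on the deviance-averaged-over-n scale.
    strict : raise :class:`ConvergenceError` when the coefficient change has
        not fallen below ``tol`` within ``max_iter`` outer iterations; with
        ``strict=False`` the last iterate is returned with
        ``converged=False`` (useful inside grid search where an unpenalized
        fit on separable fold data diverges by construction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (0.0 <= alpha <= 1.0):
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha!r}")
    if lam < 0:
        raise ConfigError(f"lambda must be >= 0, got {lam!r}")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigError("labels must be binary 0/1")
    n, p = X.shape
    beta = np.zeros(p)
    pbar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    beta0 = float(np.log(pbar / (1 - pbar)))
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = beta0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(mu * (1.0 - mu), _MIN_WEIGHT)
        z = eta + (y - mu) / w
        # weighted coordinate descent on the penalized WLS surrogate
        old = beta.copy()
        old0 = beta0
        for _ in range(100):
            max_delta = 0.0
            r = z - beta0 - X @ beta
            for j in range(p):
                r += X[:, j] * beta[j]
                zj = float(np.dot(w * X[:, j], r)) / n
                denom = float(np.dot(w, X[:, j] ** 2)) / n + l2
                new = _soft(zj, l1) / denom if denom > 0 else 0.0
                max_delta = max(max_delta, abs(new - beta[j]))
                beta[j] = new
                r -= X[:, j] * beta[j]
            new0 = beta0 + float(np.dot(w, r)) / float(np.sum(w))
            max_delta = max(max_delta, abs(new0 - beta0))
            r += beta0 - new0
            beta0 = new0
            if max_delta < tol * 0.1:
                break
        outer_delta = max(np.max(np.abs(beta - old)) if p else 0.0, abs(beta0 - old0))
        if outer_delta < tol:
            converged = True
            break
    if strict and not converged:
        raise ConvergenceError(
            f"elastic net did not converge in {max_iter} IRLS iterations "
            f"(alpha={alpha}, lambda={lam}, last coefficient change {outer_delta:.3e}, "
            f"max |beta|={np.max(np.abs(beta)) if p else 0:.3g})"
        )
    return EnetFit(beta, float(beta0), float(alpha), float(lam), it, converged)
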