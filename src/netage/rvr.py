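"""Relevance vector regression over linear-kernel bases.

Sparse Bayesian linear regression in the style of Tipping's relevance
vector machine: the design matrix is ``[1 | K_train]`` (a bias column plus
one kernel basis per training subject), each weight w_i carries its own
Gaussian prior precision alpha_i, and the hyperparameters are re-estimated
by evidence maximization:

    Sigma = (sigma^-2 Phi^T Phi + diag alpha)^-1
    mu    = sigma^-2 Sigma Phi^T y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    sigma^2 <- ||y - Phi mu||^2 / (N - sum gamma)

Bases whose precision exceeds ``alpha_prune`` are removed (their posterior
weight is pinned at zero); iteration stops when the largest relative change
in log alpha falls below ``tol``.  If every basis (including the bias) is
pruned the fit degenerates to the null model that predicts zero, which is
the correct limit for all-zero targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass(frozen=True)
class RvrOptions:
    max_iter: int = 1000
    alpha_prune: float = 1e12
    tol: float = 1e-6
    alpha_init: float = 1.0
    sigma2_init_frac: float = 0.1  # sigma2_0 = frac * var(y)


@dataclass
class RvrState:
    """Fitted RVR model: active bases, posterior weights, hyperparameters.

    ``active`` indexes columns of the full design [1 | K]; index 0 is the
    bias.  ``mu``/``sigma``/``gamma`` are aligned with ``active``.
    """

    active: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray  # posterior covariance on the active set
    alpha: np.ndarray
    sigma2: float
    gamma: np.ndarray
    converged: bool
    n_train: int
    n_iter: int
    evidence_path: list[float] = field(default_factory=list, repr=False)

    @property
    def null_model(self) -> bool:
        return self.active.size == 0

    @property
    def n_relevance_vectors(self) -> int:
        """Active kernel bases (the bias column does not count)."""
        return int((self.active > 0).sum())


def _robust_cho_factor(a: np.ndarray):
    """Cholesky with escalating diagonal-relative jitter.

    Sigma^-1 inherits the (squared) conditioning of the kernel, which for
    near-collinear bases can dip below float64 resolution; a jitter that is
    tiny relative to the diagonal restores positive definiteness without
    visibly moving the posterior.
    """
    scale = max(float(np.abs(np.diag(a)).max()), 1.0)
    jitter = 0.0
    for _ in range(12):
        try:
            return cho_factor(
                a + jitter * np.eye(a.shape[0]) if jitter else a, lower=True
            )
        except np.linalg.LinAlgError:
            jitter = scale * 1e-14 if jitter == 0 else jitter * 10
    raise np.linalg.LinAlgError(
        "posterior precision matrix not positive definite even with jitter"
    )


def fit_rvr(
    k_train: np.ndarray, y: np.ndarray, opts: RvrOptions | None = None
) -> RvrState:
    """Fit RVR on the training similarity matrix by evidence re-estimation."""
    opts = opts or RvrOptions()
    y = np.asarray(y, dtype=np.float64).ravel()
    k_train = np.asarray(k_train, dtype=np.float64)
    if k_train.ndim != 2 or k_train.shape[0] != k_train.shape[1]:
        raise ValueError(f"K_train must be square, got {k_train.shape}")
    n = y.size
    if n != k_train.shape[0]:
        raise ValueError(f"len(y)={n} does not match K side {k_train.shape[0]}")
    if not np.isfinite(y).all() or not np.isfinite(k_train).all():
        raise ValueError("inputs contain NaN or infinite values")

    phi = np.empty((n, n + 1), dtype=np.float64)
    phi[:, 0] = 1.0
    phi[:, 1:] = k_train

    active = np.arange(n + 1)
    alpha = np.full(n + 1, opts.alpha_init, dtype=np.float64)
    sigma2 = max(opts.sigma2_init_frac * float(y.var()), 1e-12)

    evidence_path: list[float] = []
    converged = False
    mu = np.zeros(0)
    sigma = np.zeros((0, 0))
    gamma = np.zeros(0)
    it = 0
    yty = float(y @ y)
    for it in range(1, opts.max_iter + 1):
        if active.size == 0:
            break
        phi_a = phi[:, active]
        pp = phi_a.T @ phi_a
        py = phi_a.T @ y
        sigma_inv = pp / sigma2 + np.diag(alpha[active])
        chol, lower = _robust_cho_factor(sigma_inv)
        sigma = cho_solve((chol, lower), np.eye(active.size))
        mu = cho_solve((chol, lower), py) / sigma2

        # log evidence at the current (alpha, sigma2)
        logdet_sigma_inv = 2.0 * np.log(np.diag(chol)).sum()
        logdet_c = (
            n * np.log(sigma2) - np.log(alpha[active]).sum() + logdet_sigma_inv
        )
        y_cinv_y = (yty - float(py @ mu)) / sigma2
        evidence_path.append(
            -0.5 * (n * np.log(2 * np.pi) + logdet_c + y_cinv_y)
        )

        gamma = np.clip(1.0 - alpha[active] * np.diag(sigma), 1e-12, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(mu**2 > 0, gamma / mu**2, np.inf)
        resid = y - phi_a @ mu
        denom = n - float(gamma.sum())
        if denom > 0:
            sigma2 = max(float(resid @ resid) / denom, 1e-12)

        keep = np.isfinite(alpha_new) & (alpha_new < opts.alpha_prune)
        old_alpha = alpha[active].copy()
        alpha[active] = np.where(keep, alpha_new, np.inf)
        if keep.all():
            delta = np.abs(np.log(alpha_new) - np.log(old_alpha)).max()
            if delta < opts.tol:
                converged = True
                active = active[keep]
                break
        active = active[keep]

    # final posterior on the surviving set
    if active.size > 0:
        phi_a = phi[:, active]
        sigma_inv = (phi_a.T @ phi_a) / sigma2 + np.diag(alpha[active])
        chol, lower = _robust_cho_factor(sigma_inv)
        sigma = cho_solve((chol, lower), np.eye(active.size))
        mu = cho_solve((chol, lower), phi_a.T @ y) / sigma2
        gamma = 1.0 - alpha[active] * np.diag(sigma)
    else:
        mu = np.zeros(0)
        sigma = np.zeros((0, 0))
        gamma = np.zeros(0)

    return RvrState(
        active=active,
        mu=np.asarray(mu, dtype=np.float64).ravel(),
        sigma=sigma,
        alpha=alpha[active],
        sigma2=float(sigma2),
        gamma=gamma,
        converged=converged,
        n_train=n,
        n_iter=it,
        evidence_path=evidence_path,
    )


def predict_rvr(state: RvrState, k_cross: np.ndarray) -> np.ndarray:
    """Predict ages for test rows: [1 | K_cross] restricted to active bases."""
    k_cross = np.atleast_2d(np.asarray(k_cross, dtype=np.float64))
    if k_cross.shape[1] != state.n_train:
        raise ValueError(
            f"K_cross has {k_cross.shape[1]} columns, expected {state.n_train}"
        )
    if state.null_model:
        return np.zeros(k_cross.shape[0])
    phi_star = np.empty((k_cross.shape[0], state.active.size))
    for j, col in enumerate(state.active):
        phi_star[:, j] = 1.0 if col == 0 else k_cross[:, col - 1]
    return phi_star @ state.mu
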