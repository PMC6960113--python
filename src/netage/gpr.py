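"""Gaussian process regression on a precomputed linear-kernel matrix.

The model is ``y = mu0 + f + eps`` with a constant mean fixed to the
training mean, a GP prior ``f ~ N(0, theta2 * K)`` over the training
similarity matrix K, and iid noise ``eps ~ N(0, sigma2)``.  The two
hyperparameters (signal scale theta2, noise variance sigma2) are chosen by
maximizing the log marginal likelihood over log-parameters from three
documented starting points; with both supplied and ``optimize=False`` the
model reduces to kernel ridge regression with penalty sigma2 / theta2.

Because K is fixed, it is eigendecomposed once and every marginal-likelihood
evaluation (and its analytic gradient) costs O(n^2); predictions use the
standard conditional mean ``mu0 + theta2 * K_cross @ inv(theta2 K +
sigma2 I) @ (y - mu0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize


class NotPositiveSemidefiniteError(ValueError):
    """Kernel matrix has eigenvalues below the jitter tolerance."""


@dataclass(frozen=True)
class GprOptions:
    """Fitting options; ``theta2``/``sigma2`` fix a hyperparameter."""

    theta2: float | None = None
    sigma2: float | None = None
    optimize: bool = True
    jitter_scale: float = 1e-8  # jitter = scale * trace(K) / n on K's diagonal
    max_iter: int = 200
    # Double-center K in feature space (phi(x) - train mean phi).  Removes
    # the dominant constant-image direction, without which a single shared
    # signal scale cannot favor the age axis on small cohorts.
    center_kernel: bool = False


@dataclass
class GprState:
    """Fitted GPR model (hyperparameters + cached training solve)."""

    theta2: float
    sigma2: float
    mu0: float
    alpha: np.ndarray  # (theta2 K + sigma2 I)^-1 (y - mu0)
    log_marginal_likelihood: float
    converged: bool
    n_train: int
    lml_path: list[float] = field(default_factory=list, repr=False)
    # kernel-centering statistics (None when centering is off)
    col_means: np.ndarray | None = None
    total_mean: float = 0.0


def _eig_kernel(k: np.ndarray, jitter_scale: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.asarray(k, dtype=np.float64)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"K must be square, got {k.shape}")
    if not np.allclose(k, k.T, rtol=0, atol=1e-8 * max(1.0, np.abs(k).max())):
        raise ValueError("K must be symmetric")
    evals, evecs = np.linalg.eigh(k)
    n = k.shape[0]
    # PSD tolerance is fixed relative to the trace (independent of the
    # jitter setting): eigenvalues at the rounding floor are clipped to 0
    tol = 1e-10 * max(np.trace(k), 1.0)
    if evals.min() < -tol:
        raise NotPositiveSemidefiniteError(
            f"K has eigenvalue {evals.min():.3g} below tolerance -{tol:.3g}"
        )
    jitter = jitter_scale * np.trace(k) / n
    evals = np.clip(evals, 0.0, None) + jitter
    return evals, evecs


def _neg_lml_and_grad(
    log_params: np.ndarray, lam: np.ndarray, q2: np.ndarray, n: int
) -> tuple[float, np.ndarray]:
    """-log p(y | theta2, sigma2) and gradient w.r.t. the log parameters.

    With K = Q diag(lam) Q^T and q = Q^T (y - mu0), the covariance
    eigenvalues are d_i = theta2 lam_i + sigma2 and
    lml = -1/2 [ sum log d_i + sum q_i^2 / d_i + n log 2 pi ].
    """
    theta2, sigma2 = np.exp(log_params)
    d = theta2 * lam + sigma2
    inv_d = 1.0 / d
    lml = -0.5 * (np.log(d).sum() + (q2 * inv_d).sum() + n * np.log(2 * np.pi))
    # d lml / d theta2 = 1/2 sum (q_i^2/d_i^2 - 1/d_i) lam_i ; chain by theta2
    common = q2 * inv_d**2 - inv_d
    g_theta = 0.5 * float((common * lam).sum()) * theta2
    g_sigma = 0.5 * float(common.sum()) * sigma2
    return -lml, -np.array([g_theta, g_sigma])


def fit_gpr(
    k_train: np.ndarray, y: np.ndarray, opts: GprOptions | None = None
) -> GprState:
    """Fit the GP by maximizing the log marginal likelihood.

    Three starts (in units of the data variance s and mean kernel diagonal
    kappa): (theta2, sigma2) = (s/kappa, 0.1 s), (s/kappa, s) and
    (0.1 s/kappa, 0.5 s).  Starts are skipped for any hyperparameter fixed
    in ``opts``.
    """
    opts = opts or GprOptions()
    y = np.asarray(y, dtype=np.float64).ravel()
    k_train = np.asarray(k_train, dtype=np.float64)
    col_means = None
    total_mean = 0.0
    if opts.center_kernel:
        col_means = k_train.mean(axis=0)
        total_mean = float(k_train.mean())
        k_train = (
            k_train - col_means[None, :] - col_means[:, None] + total_mean
        )
    lam, evecs = _eig_kernel(k_train, opts.jitter_scale)
    n = y.size
    if n != lam.size:
        raise ValueError(f"len(y)={n} does not match K side {lam.size}")
    mu0 = float(y.mean())
    r = y - mu0
    q = evecs.T @ r
    q2 = q**2

    s = max(float(r.var()), 1e-12)
    kappa = max(float(lam.mean()), 1e-300)

    fixed_t, fixed_s = opts.theta2, opts.sigma2
    if fixed_t is not None and fixed_s is not None and not opts.optimize:
        theta2, sigma2 = float(fixed_t), float(fixed_s)
        nll, _ = _neg_lml_and_grad(np.log([theta2, sigma2]), lam, q2, n)
        state = _make_state(theta2, sigma2, mu0, r, lam, evecs, -nll, True, n)
        state.col_means, state.total_mean = col_means, total_mean
        return state

    starts = [
        (s / kappa, 0.1 * s),
        (s / kappa, s),
        (0.1 * s / kappa, 0.5 * s),
    ]
    best = None
    lml_path: list[float] = []
    converged = False
    for t0, s0 in starts:
        x0 = np.log(
            [fixed_t if fixed_t is not None else t0,
             fixed_s if fixed_s is not None else s0]
        )

        def obj(x):
            # respect fixed hyperparameters by overwriting coordinates
            xx = x.copy()
            if fixed_t is not None:
                xx[0] = np.log(fixed_t)
            if fixed_s is not None:
                xx[1] = np.log(fixed_s)
            nll, grad = _neg_lml_and_grad(xx, lam, q2, n)
            if fixed_t is not None:
                grad[0] = 0.0
            if fixed_s is not None:
                grad[1] = 0.0
            return nll, grad

        # record the LML at accepted iterates only (line-search probes are
        # not monotone; accepted L-BFGS-B steps are)
        path: list[float] = [-obj(x0)[0]]
        bounds = [(x - 30.0, x + 30.0) for x in x0]  # keep exp() finite
        res = minimize(
            obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            callback=lambda xk: path.append(-obj(xk)[0]),
            options={"maxiter": opts.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
            lml_path = path
        converged = converged or bool(res.success)

    assert best is not None
    xx = best.x.copy()
    if fixed_t is not None:
        xx[0] = np.log(fixed_t)
    if fixed_s is not None:
        xx[1] = np.log(fixed_s)
    theta2, sigma2 = np.exp(xx)
    state = _make_state(
        float(theta2), float(sigma2), mu0, r, lam, evecs, -best.fun, converged, n
    )
    state.lml_path = lml_path
    state.col_means, state.total_mean = col_means, total_mean
    return state


def _make_state(theta2, sigma2, mu0, r, lam, evecs, lml, converged, n) -> GprState:
    d = theta2 * lam + sigma2
    alpha = evecs @ ((evecs.T @ r) / d)
    return GprState(
        theta2=theta2,
        sigma2=sigma2,
        mu0=mu0,
        alpha=alpha,
        log_marginal_likelihood=float(lml),
        converged=converged,
        n_train=n,
    )


def predict_gpr(state: GprState, k_cross: np.ndarray) -> np.ndarray:
    """Posterior mean ages for test rows: mu0 + theta2 K_cross alpha."""
    k_cross = np.atleast_2d(np.asarray(k_cross, dtype=np.float64))
    if k_cross.shape[1] != state.n_train:
        raise ValueError(
            f"K_cross has {k_cross.shape[1]} columns, expected {state.n_train}"
        )
    if state.col_means is not None:
        k_cross = (
            k_cross
            - k_cross.mean(axis=1, keepdims=True)
            - state.col_means[None, :]
            + state.total_mean
        )
    return state.mu0 + state.theta2 * (k_cross @ state.alpha)
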