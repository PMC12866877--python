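"""Scalar Gaussian-process regression for reduced coefficients.

One GP per principal-component coefficient: zero prior mean, squared
exponential (RBF) kernel

    c(x, x') = sigma_k^2 exp(-|x - x'|^2 / (2 l^2)),

plus an i.i.d. Gaussian noise variance sigma^2 on the targets.  The
hyperparameters theta = (sigma_k, l, sigma) are chosen by minimising the
negative log marginal likelihood (NLML)

    L(theta) = 1/2 y^T C^-1 y + 1/2 log|C| + d/2 log(2 pi),
    C = C_k(theta) + sigma^2 I,

with Polak-Ribiere nonlinear conjugate gradient in log-hyperparameter
space (so positivity is automatic) and a backtracking Armijo line search.
Posterior prediction follows the standard Gaussian conditional, with the
noise variance entering both the training covariance and the predictive
variance.

Inputs are column-per-sample: a training design is ``(I, n1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.linalg.lapack import dpotri
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "GPHyperparameters",
    "GPFitOptions",
    "ComponentGP",
    "PosteriorPrediction",
    "rbf_kernel",
    "kernel_matrix",
    "nlml",
    "nlml_gradient",
    "optimize_hyperparameters",
    "fit_component",
    "posterior_predict",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel amplitude, length scale and observation-noise std."""

    signal_std: float
    length_scale: float
    noise_std: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.signal_std) and self.signal_std > 0):
            raise ValueError("signal_std must be finite and > 0")
        if not (np.isfinite(self.length_scale) and self.length_scale > 0):
            raise ValueError("length_scale must be finite and > 0")
        if not (np.isfinite(self.noise_std) and self.noise_std >= 0):
            raise ValueError("noise_std must be finite and >= 0")


@dataclass(frozen=True)
class GPFitOptions:
    """Optimizer and numerics settings for hyperparameter fitting.

    ``grad_tol`` is the convergence criterion on the log-space gradient
    norm; independently, the search stops once the NLML improves by less
    than ``stall_rel_tol * (|NLML| + 1)`` over ``stall_window``
    consecutive iterations (flat ridges of the marginal likelihood are
    common and polishing them does not change predictions).
    ``n_restarts`` seeded log-uniform (x0.1 .. x10) perturbations of
    the data-driven initial point are screened by their NLML and conjugate
    gradient is run from the best start (remaining starts are fallbacks if
    that run fails to improve).  ``noise_floor_rel`` floors the optimized
    noise std at a fraction of the target standard deviation.  Setting any
    ``fixed_*`` value removes that hyperparameter from the optimization.
    """

    grad_tol: float = 1e-6
    max_iter: int = 500
    stall_window: int = 15
    stall_rel_tol: float = 1e-5
    armijo_c1: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 50
    n_restarts: int = 3
    restart_log_range: float = math.log(10.0)
    seed: int = 0
    noise_floor_rel: float = 1e-6
    jitter_rel: float = 1e-10
    jitter_max_rel: float = 1e-4
    fixed_signal_std: float | None = None
    fixed_length_scale: float | None = None
    fixed_noise_std: float | None = None


@dataclass
class PosteriorPrediction:
    """Posterior mean and (clamped, non-negative) variance per test point."""

    mean: np.ndarray
    variance: np.ndarray


@dataclass
class ComponentGP:
    """A fitted scalar GP: hyperparameters plus cached factorization."""

    hyper: GPHyperparameters
    train_inputs: np.ndarray  # (I, n1), normalized
    train_targets: np.ndarray  # (n1,)
    chol_lower: np.ndarray
    weights: np.ndarray  # (C11 + sigma^2 I + jitter)^-1 y
    jitter: float
    nlml_value: float
    converged: bool = True
    n_iter: int = 0


# ---------------------------------------------------------------------------
# kernels


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("inputs must be an (I, n) matrix")
    return X


def rbf_kernel(x: np.ndarray, x_prime: np.ndarray, hyper: GPHyperparameters) -> float:
    """Squared-exponential covariance between two input vectors."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x_prime = np.atleast_1d(np.asarray(x_prime, dtype=float))
    if x.shape != x_prime.shape:
        raise ValueError("input vectors must have the same dimension")
    sq = float(np.sum((x - x_prime) ** 2))
    return hyper.signal_std**2 * math.exp(-sq / (2.0 * hyper.length_scale**2))


def _sqdist(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    X = _as_design(X)
    if Y is None:
        return cdist(X.T, X.T, "sqeuclidean")
    return cdist(_as_design(Y).T, X.T, "sqeuclidean")


def kernel_matrix(X: np.ndarray, hyper: GPHyperparameters) -> np.ndarray:
    """Dense d x d RBF covariance matrix of the design ``X`` (I x d)."""
    D2 = _sqdist(X)
    return hyper.signal_std**2 * np.exp(-D2 / (2.0 * hyper.length_scale**2))


# ---------------------------------------------------------------------------
# marginal likelihood


def _chol_with_jitter(C: np.ndarray, opts: GPFitOptions):
    """Cholesky with escalating diagonal jitter; returns (L, jitter)."""
    scale = float(np.mean(np.diag(C)))
    if scale <= 0:
        scale = 1.0
    jitter = opts.jitter_rel * scale
    A = C + jitter * np.eye(C.shape[0])
    while True:
        try:
            L = np.linalg.cholesky(A)
            return L, jitter
        except np.linalg.LinAlgError:
            if jitter >= opts.jitter_max_rel * scale:
                raise np.linalg.LinAlgError(
                    "kernel matrix not factorizable even at maximum jitter"
                )
            new_jitter = jitter * 10.0
            warnings.warn(
                f"Cholesky failed; escalating jitter to {new_jitter:.3e}",
                RuntimeWarning,
            )
            A += (new_jitter - jitter) * np.eye(C.shape[0])
            jitter = new_jitter


_LOG_BOUND = 40.0  # |log theta| beyond this is numerically meaningless


def _nlml_core(t: np.ndarray, D2: np.ndarray, y: np.ndarray, opts: GPFitOptions,
               want_grad: bool):
    """NLML (and gradient w.r.t. log-hyperparameters) at t = log theta.

    Returns ``(inf, None, 0.0)`` for iterates outside the representable
    log-range or whose covariance cannot be factorized, so the line
    search simply backtracks away from them.
    """
    if np.max(t) > _LOG_BOUND or t[1] < -_LOG_BOUND:
        return np.inf, None, 0.0
    log_sk, log_l, log_s = t
    sk2 = math.exp(2.0 * log_sk)
    l2 = math.exp(2.0 * log_l)
    s2 = math.exp(2.0 * log_s)
    d = y.shape[0]
    K = sk2 * np.exp(-D2 / (2.0 * l2))
    C = K + s2 * np.eye(d)
    try:
        L, jitter = _chol_with_jitter(C, opts)
    except np.linalg.LinAlgError:
        if want_grad:
            raise
        return np.inf, None, 0.0
    alpha = cho_solve((L, True), y)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    f = 0.5 * float(y @ alpha) + 0.5 * logdet + 0.5 * d * _LOG2PI
    if not want_grad:
        return f, None, jitter
    Cinv, info = dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - dpotri failure implies a bad factor
        Cinv = cho_solve((L, True), np.eye(d))
    else:
        Cinv = Cinv + np.tril(Cinv, -1).T  # dpotri fills one triangle
    # dL/dtheta = 1/2 tr((Cinv - alpha alpha^T) dC/dtheta)
    A = Cinv - np.outer(alpha, alpha)
    dK_dlog_l = K * (D2 / l2)
    g = np.array([
        float(np.sum(A * K)),                 # dC/dlog sk = 2K -> 1/2*tr(A*2K)
        0.5 * float(np.sum(A * dK_dlog_l)),   # dC/dlog l
        s2 * float(np.trace(A)),              # dC/dlog s = 2 s^2 I
    ])
    return f, g, jitter


def nlml(hyper: GPHyperparameters, train_inputs: np.ndarray,
         train_targets: np.ndarray, opts: GPFitOptions | None = None) -> float:
    """Negative log marginal likelihood of the targets under ``hyper``."""
    opts = opts or GPFitOptions()
    y = np.asarray(train_targets, dtype=float).ravel()
    D2 = _sqdist(train_inputs)
    t = _to_log(hyper)
    f, _, _ = _nlml_core(t, D2, y, opts, want_grad=False)
    return f


def nlml_gradient(hyper: GPHyperparameters, train_inputs: np.ndarray,
                  train_targets: np.ndarray,
                  opts: GPFitOptions | None = None) -> np.ndarray:
    """Gradient of the NLML w.r.t. (log sigma_k, log l, log sigma)."""
    opts = opts or GPFitOptions()
    y = np.asarray(train_targets, dtype=float).ravel()
    D2 = _sqdist(train_inputs)
    t = _to_log(hyper)
    _, g, _ = _nlml_core(t, D2, y, opts, want_grad=True)
    return g


_MIN_LOG_NOISE = math.log(1e-300)


def _to_log(hyper: GPHyperparameters) -> np.ndarray:
    log_noise = (
        math.log(hyper.noise_std) if hyper.noise_std > 0 else _MIN_LOG_NOISE
    )
    return np.array([
        math.log(hyper.signal_std), math.log(hyper.length_scale), log_noise
    ])


def _from_log(t: np.ndarray) -> GPHyperparameters:
    noise = math.exp(t[2]) if t[2] > _MIN_LOG_NOISE else 0.0
    return GPHyperparameters(
        signal_std=math.exp(t[0]), length_scale=math.exp(t[1]), noise_std=noise
    )


# ---------------------------------------------------------------------------
# optimization


def _cg_minimize(fg, t0: np.ndarray, free: np.ndarray, lower: np.ndarray,
                 opts: GPFitOptions):
    """Polak-Ribiere CG with Armijo backtracking, on the free coordinates.

    ``lower`` is an elementwise lower bound (used for the noise floor);
    iterates are projected onto it and bound-active descent components are
    ignored in the convergence test.
    """
    n_free = int(free.sum())
    restart_every = max(1, 3 * n_free)
    t = np.maximum(t0, lower)
    f, g, _ = fg(t)
    g = np.where(free, g, 0.0)
    d = -g
    step = 1.0
    n_iter = 0
    stall = 0
    stall_resets = 0
    window_f = f
    flat_windows = 0
    for n_iter in range(1, opts.max_iter + 1):
        if n_iter % opts.stall_window == 0:
            if window_f - f < opts.stall_rel_tol * (abs(f) + 1.0):
                flat_windows += 1
                if flat_windows >= 2:
                    return t, f, False, n_iter
            else:
                flat_windows = 0
            window_f = f
        g_eff = np.where((t <= lower) & (g > 0), 0.0, g)
        if np.linalg.norm(g_eff) < opts.grad_tol:
            return t, f, True, n_iter - 1
        if d @ g >= 0:
            d = -g
        slope = float(d @ g)
        # Armijo backtracking from an adaptive initial step
        a = step
        accepted = False
        for _ in range(opts.max_backtracks):
            t_new = np.maximum(t + a * d, lower)
            f_new, _, _ = fg(t_new, want_grad=False)
            if f_new <= f + opts.armijo_c1 * a * slope:
                accepted = True
                break
            a *= opts.backtrack_factor
        if not accepted:
            if not np.allclose(d, -g):
                d = -g  # retry along steepest descent
                step = 1.0
                continue
            return t, f, False, n_iter
        step = min(max(a * 2.0, 1e-8), 4.0)
        t_new = np.maximum(t + a * d, lower)
        f_new, g_new, _ = fg(t_new)
        g_new = np.where(free, g_new, 0.0)
        if f - f_new < 1e-12 * (abs(f) + 1.0):
            stall += 1
            if stall >= 3:
                if stall_resets >= 2:
                    return t_new, f_new, False, n_iter
                # plateau may be an artifact of a poor CG direction: give
                # a fresh steepest-descent restart a chance before quitting
                stall_resets += 1
                stall = 0
                t, f, g = t_new, f_new, np.where(free, g_new, 0.0)
                d = -g
                step = 1.0
                continue
        else:
            stall = 0
        beta = float(g_new @ (g_new - g)) / float(g @ g)
        if beta < 0 or n_iter % restart_every == 0:
            beta = 0.0  # restart with steepest descent
        d = -g_new + beta * d
        t, f, g = t_new, f_new, g_new
    return t, f, False, opts.max_iter


def _default_init(X: np.ndarray, y: np.ndarray,
                  opts: GPFitOptions) -> GPHyperparameters:
    y_std = float(np.std(y))
    scale = max(y_std, 1e-3 * float(np.sqrt(np.mean(y**2))), 1e-12)
    n = X.shape[1]
    if n > 1:
        if n > 600:  # median of a subsample is enough for an initial guess
            idx = np.linspace(0, n - 1, 600).astype(int)
            dists = pdist(X[:, idx].T)
        else:
            dists = pdist(X.T)
        med = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0
    else:
        med = 1.0
    return GPHyperparameters(
        signal_std=opts.fixed_signal_std or scale,
        length_scale=opts.fixed_length_scale or med,
        noise_std=(
            opts.fixed_noise_std
            if opts.fixed_noise_std is not None
            else 0.05 * scale
        ),
    )


def optimize_hyperparameters(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    init: GPHyperparameters | None = None,
    opts: GPFitOptions | None = None,
):
    """Minimise the NLML over the (free) log-hyperparameters.

    Returns ``(hyper, info)`` where ``info`` carries ``nlml``,
    ``converged``, ``n_iter`` and the gradient norm at the solution.  The
    returned NLML never exceeds the NLML of the initial point.
    """
    opts = opts or GPFitOptions()
    X = _as_design(train_inputs)
    y = np.asarray(train_targets, dtype=float).ravel()
    if X.shape[1] != y.shape[0]:
        raise ValueError("train_inputs and train_targets sizes disagree")
    if y.shape[0] < 2:
        raise ValueError("need at least two training points")
    D2 = _sqdist(X)

    if init is None:
        init = _default_init(X, y, opts)

    free = np.array([
        opts.fixed_signal_std is None,
        opts.fixed_length_scale is None,
        opts.fixed_noise_std is None,
    ])
    y_std = float(np.std(y))
    noise_floor = opts.noise_floor_rel * max(y_std, 1e-12)
    lower = np.array([-np.inf, -np.inf, -np.inf])
    if free[2]:
        lower[2] = math.log(noise_floor)

    def fg(t, want_grad=True):
        return _nlml_core(t, D2, y, opts, want_grad)

    t0 = np.maximum(_to_log(init), lower)
    f0, _, _ = fg(t0, want_grad=False)

    rng = np.random.default_rng(opts.seed)
    starts = [t0]
    for _ in range(opts.n_restarts):
        pert = rng.uniform(-opts.restart_log_range, opts.restart_log_range, 3)
        starts.append(np.maximum(t0 + np.where(free, pert, 0.0), lower))
    # screen starts by NLML, run CG from the most promising one first
    start_f = [f0] + [fg(s, want_grad=False)[0] for s in starts[1:]]
    order = np.argsort(start_f)

    best_t, best_f, best_conv, best_iter = t0, f0, False, 0
    improved = False
    for rank, idx in enumerate(order):
        t_hat, f_hat, conv, n_it = _cg_minimize(fg, starts[idx], free, lower, opts)
        if f_hat < best_f:
            best_t, best_f, best_conv, best_iter = t_hat, f_hat, conv, n_it
            improved = True
        elif f_hat == best_f and not improved:
            best_conv, best_iter = conv, n_it
        if improved or conv or rank == len(order) - 1:
            break  # fallback starts are only used while nothing improved
    if not improved and best_f > f0:
        warnings.warn(
            "hyperparameter optimization failed to improve on the initial "
            "point; returning the initial hyperparameters",
            RuntimeWarning,
        )
        best_t, best_f = t0, f0

    hyper = _from_log(best_t)
    if not free[2]:
        hyper = replace(hyper, noise_std=float(opts.fixed_noise_std))
    if not free[0]:
        hyper = replace(hyper, signal_std=float(opts.fixed_signal_std))
    if not free[1]:
        hyper = replace(hyper, length_scale=float(opts.fixed_length_scale))
    _, g_final, _ = _nlml_core(best_t, D2, y, opts, want_grad=True)
    info = {
        "nlml": best_f,
        "nlml_init": f0,
        "converged": bool(best_conv),
        "n_iter": int(best_iter),
        "grad_norm": float(np.linalg.norm(np.where(free, g_final, 0.0))),
    }
    return hyper, info


# ---------------------------------------------------------------------------
# fitting and prediction


def fit_component(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    opts: GPFitOptions | None = None,
    hyper: GPHyperparameters | None = None,
) -> ComponentGP:
    """Optimize hyperparameters (unless given) and cache the factorization."""
    opts = opts or GPFitOptions()
    X = _as_design(train_inputs)
    y = np.asarray(train_targets, dtype=float).ravel()
    if hyper is None:
        hyper, info = optimize_hyperparameters(X, y, opts=opts)
        converged, n_iter, nlml_value = (
            info["converged"], info["n_iter"], info["nlml"]
        )
    else:
        nlml_value = nlml(hyper, X, y, opts)
        converged, n_iter = True, 0
    C = kernel_matrix(X, hyper) + hyper.noise_std**2 * np.eye(X.shape[1])
    L, jitter = _chol_with_jitter(C, opts)
    weights = cho_solve((L, True), y)
    return ComponentGP(
        hyper=hyper,
        train_inputs=X.copy(),
        train_targets=y.copy(),
        chol_lower=L,
        weights=weights,
        jitter=jitter,
        nlml_value=nlml_value,
        converged=converged,
        n_iter=n_iter,
    )


def posterior_predict(gp: ComponentGP, test_inputs: np.ndarray) -> PosteriorPrediction:
    """Gaussian posterior at new inputs.

    mean = K21 (C11 + sigma^2 I)^-1 y,
    var  = diag(K22 + sigma^2 I - K21 (C11 + sigma^2 I)^-1 K12), clamped
    at zero.
    """
    if gp.chol_lower is None or gp.weights is None:
        raise ValueError("ComponentGP is not fitted")
    Xs = _as_design(test_inputs)
    if Xs.shape[0] != gp.train_inputs.shape[0]:
        raise ValueError("test input dimension does not match training inputs")
    D2 = _sqdist(gp.train_inputs, Xs)  # (n2, n1)
    K21 = gp.hyper.signal_std**2 * np.exp(-D2 / (2.0 * gp.hyper.length_scale**2))
    mean = K21 @ gp.weights
    V = solve_triangular(gp.chol_lower, K21.T, lower=True)
    prior_var = gp.hyper.signal_std**2 + gp.hyper.noise_std**2
    var = prior_var - np.sum(V**2, axis=0)
    var = np.clip(var, 0.0, None)
    return PosteriorPrediction(mean=mean, variance=var)
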