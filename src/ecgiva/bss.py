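"""Blind source separation: IVA variants plus ICA and CCA baselines.

Independent vector analysis (IVA) jointly un-mixes ``D`` data sets.  The
k-th estimated source across data sets forms the *source component
vector* (SCV) ``y_k = (y_k^1, ..., y_k^D)``; IVA minimises the mutual
information between SCVs,

    I_IVA = sum_k ( sum_d H[y_k^d] - I[y_k] ) - sum_d log|det W^d| - C,

which this module realises, as is standard, through the negative
log-likelihood of a chosen SCV prior (the data-dependent constant C is
dropped):

* ``iva_g``   — multivariate Gaussian prior: only second-order structure
  (the D x D covariance of each SCV) drives separation;
* ``iva_l``   — multivariate Laplacian prior: higher-order statistics via
  the score ``y_k^d / sqrt(sum_d (y_k^d)^2)``, no second-order coupling;
* ``iva_ggd`` — multivariate generalized Gaussian prior with shape
  ``beta``: both second- and higher-order statistics (``beta=1``
  recovers the Gaussian update direction).

All three run the same natural-gradient descent with per-iteration row
normalisation (unit-variance outputs) and backtracking step halving, so
the recorded cost trace is non-increasing by construction.

``fastica`` (single data set, tanh contrast) and ``cca_bss`` (separation
by joint diagonalisation of the zero-lag and lagged covariance, the
classic second-order route) serve as the comparison baselines.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn
from sklearn.decomposition import FastICA as _SKFastICA
from sklearn.exceptions import ConvergenceWarning

from .core import AlgorithmOptions, DataSetCollection, UnmixingResult

__all__ = [
    "whiten",
    "iva_cost",
    "iva_g",
    "iva_l",
    "iva_ggd",
    "fastica",
    "cca_bss",
]

#: diagonal loading of SCV covariances inside the optimisers, as a fraction
#: of the mean SCV variance.  The delayed data sets make true SCV
#: covariances nearly singular; loading at about the sensor-noise floor
#: stops the log-det term from rewarding degenerate max-correlation
#: directions that do not correspond to sources.
DEFAULT_SCV_RIDGE = 0.02

#: GGD shapes are re-estimated from the marginal kurtosis only during the
#: first few iterations, then frozen so the objective is fixed thereafter.
_BETA_UPDATE_ITERS = 5


def whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sphere a K x L data matrix: ``Z = V @ (X - mean)`` with cov(Z) = I.

    Returns ``(Z, V)``.  Raises on rank-deficient input (e.g. duplicated
    channels), naming the effective rank.
    """
    X = np.asarray(X, dtype=float)
    K, L = X.shape
    if L <= K:
        raise ValueError(f"need more samples than channels, got {K}x{L}")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / L
    evals, evecs = eigh(C)
    tol = max(K, L) * np.finfo(float).eps * evals.max()
    rank = int(np.sum(evals > tol))
    if rank < K:
        raise np.linalg.LinAlgError(
            f"input is rank deficient: {rank} independent channels out of {K}"
        )
    V = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric (ZCA) whitener
    return V @ Xc, V


def _as_arrays(X) -> list[np.ndarray]:
    if isinstance(X, DataSetCollection):
        return [np.asarray(ds.mixed, float) for ds in X.datasets]
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return [X.astype(float)]
    return [np.asarray(x, float) for x in X]


def _scv_stack(Y: list[np.ndarray]) -> np.ndarray:
    """Stack per-data-set outputs into a (K, D, L) SCV array."""
    return np.stack(Y, axis=1)


def _ggd_beta_from_kurtosis(kurt: float) -> float:
    """Invert the univariate GGD excess-kurtosis / shape relation.

    A GGD marginal with density ``exp(-|x|^s)`` has excess kurtosis
    ``G(5/s)G(1/s)/G(3/s)^2 - 3``; the multivariate exponent
    ``(y' S^-1 y)^beta`` has marginal shape ``s = 2 beta``.
    """

    def excess(s: float) -> float:
        return gamma_fn(5.0 / s) * gamma_fn(1.0 / s) / gamma_fn(3.0 / s) ** 2 - 3.0

    s_lo, s_hi = 0.5, 8.0
    k = float(np.clip(kurt, excess(s_hi) + 1e-9, excess(s_lo) - 1e-9))
    s = brentq(lambda v: excess(v) - k, s_lo, s_hi, xtol=1e-4)
    return s / 2.0


def _estimate_betas(S: np.ndarray) -> np.ndarray:
    """Kurtosis-matched GGD shape per SCV (marginal kurtosis, mean over d)."""
    m2 = np.mean(S**2, axis=2)
    m4 = np.mean(S**4, axis=2)
    kurts = np.mean(m4 / np.maximum(m2, 1e-12) ** 2 - 3.0, axis=1)
    return np.array([_ggd_beta_from_kurtosis(k) for k in kurts])


def _scv_covariances(S: np.ndarray, ridge: float) -> np.ndarray:
    """(K, D, D) sample covariances of the SCVs with diagonal loading.

    ``ridge`` is relative to the mean SCV variance, which makes the
    loaded objective invariant to a common rescaling of the outputs.
    """
    K, D, L = S.shape
    C = np.einsum("kdl,kel->kde", S, S) / L
    lam = np.maximum(ridge * np.trace(C, axis1=1, axis2=2) / D, 1e-14)
    return C + lam[:, None, None] * np.eye(D)


def _prior_terms(
    S: np.ndarray, prior: str, betas: np.ndarray | None, ridge: float
) -> tuple[np.ndarray, float]:
    """Score array (K, D, L) and SCV-prior cost for the current outputs.

    The score is the exact gradient of the returned cost through the
    sample statistics (including the covariance and the ridge), so a
    backtracking line search on this cost is guaranteed a descent
    direction.
    """
    K, D, L = S.shape
    if prior == "gaussian":
        C = np.einsum("kdl,kel->kde", S, S) / L
        tr = np.trace(C, axis1=1, axis2=2)
        lam = np.maximum(ridge * tr / D, 1e-14)
        Cr = C + lam[:, None, None] * np.eye(D)
        Cinv = np.linalg.inv(Cr)
        score = np.einsum("kde,kel->kdl", Cinv, S)
        if ridge > 0:
            # d lam/dy contributes (ridge/D) tr(Cinv) * (2/L) y
            tr_inv = np.trace(Cinv, axis1=1, axis2=2)
            score = score + (ridge / D) * tr_inv[:, None, None] * S
        cost = 0.5 * float(np.sum(np.linalg.slogdet(Cr)[1]))
        return score, cost
    if prior == "laplacian":
        r = np.sqrt(np.sum(S**2, axis=1, keepdims=True) + 1e-12)
        score = S / r
        cost = float(np.sum(np.mean(r[:, 0, :], axis=-1)))
        return score, cost
    if prior == "ggd":
        if betas is None:
            betas = _estimate_betas(S)
        C = _scv_covariances(S, ridge)
        Cinv = np.linalg.inv(C)
        CiS = np.einsum("kde,kel->kdl", Cinv, S)
        q = np.einsum("kdl,kdl->kl", S, CiS) + 1e-12
        qb = q ** (betas[:, None] - 1.0)
        # full gradient of mean(q^beta)/2 + logdet(C)/2 through the sample
        # covariance: at beta=1 the three terms collapse to the Gaussian score
        M = np.einsum("kdl,kl,kel->kde", S, qb, S) / L  # sum_t q^(b-1) y y' / L
        CiMCi = np.einsum("kde,kef,kfg->kdg", Cinv, M, Cinv)
        corr = np.einsum("kde,kel->kdl", CiMCi, S)
        score = betas[:, None, None] * (qb[:, None, :] * CiS - corr) + CiS
        if ridge > 0:
            # chain rule through the trace-proportional loading
            tr_inv = np.trace(Cinv, axis1=1, axis2=2)
            u = np.mean(qb * np.sum(CiS**2, axis=1), axis=1)
            c_lam = 0.5 * tr_inv - 0.5 * betas * u
            score = score + (2.0 * ridge / D) * c_lam[:, None, None] * S
        cost = float(
            np.sum(0.5 * np.mean(q ** betas[:, None], axis=1))
            + 0.5 * np.sum(np.linalg.slogdet(C)[1])
        )
        return score, cost
    raise ValueError(f"unknown prior {prior!r}")


def _cost_from_outputs(
    S: np.ndarray, W: list[np.ndarray], prior: str, betas, ridge: float
) -> float:
    _, prior_cost = _prior_terms(S, prior, betas, ridge)
    logdets = sum(float(np.linalg.slogdet(Wd)[1]) for Wd in W)
    return prior_cost - logdets


def iva_cost(
    W: list[np.ndarray],
    X,
    prior: str = "gaussian",
    beta: float | str = 1.0,
    ridge: float = 0.0,
) -> float:
    """Evaluate the IVA objective (up to its data constant) for given W.

    ``prior`` selects the SCV model: ``"gaussian"`` scores each SCV by
    ``1/2 log det`` of its D x D sample covariance, ``"laplacian"`` by
    the mean SCV 2-norm, ``"ggd"`` by the generalized Gaussian
    negative log-likelihood with shape ``beta`` (a scalar, or
    ``"estimate"`` for kurtosis matching).  ``ridge`` applies the same
    relative diagonal loading the optimisers use (their objective is
    reproduced by passing ``AlgorithmOptions.scv_ridge``).
    """
    Xs = _as_arrays(X)
    W = [np.asarray(w, float) for w in W]
    if len(W) != len(Xs):
        raise ValueError("one un-mixing matrix per data set required")
    for w, x in zip(W, Xs):
        if w.shape[0] != w.shape[1] or w.shape[1] != x.shape[0]:
            raise ValueError("W/X shape mismatch")
        if abs(np.linalg.det(w)) < 1e-300:
            raise np.linalg.LinAlgError("singular un-mixing matrix")
    Y = [w @ (x - x.mean(axis=1, keepdims=True)) for w, x in zip(W, Xs)]
    S = _scv_stack(Y)
    betas = None
    if prior == "ggd" and beta != "estimate":
        betas = np.full(S.shape[0], float(beta))
    return _cost_from_outputs(S, W, prior, betas, ridge)


def _init_unmixing(K: int, D: int, opts: AlgorithmOptions) -> list[np.ndarray]:
    if opts.init == "identity":
        return [np.eye(K) for _ in range(D)]
    if opts.init == "random":
        rng = np.random.default_rng(opts.seed)
        out = []
        for _ in range(D):
            Q, _ = np.linalg.qr(rng.standard_normal((K, K)))
            out.append(Q)
        return out
    raise ValueError(f"unknown init {opts.init!r}")


def _finalize(
    W_white: list[np.ndarray],
    whiteners: list[np.ndarray] | None,
    Xs: list[np.ndarray],
    n_iter: int,
    converged: bool,
    algorithm: str,
    trace: list[float],
) -> UnmixingResult:
    """Undo whitening, normalise scale/sign, and assemble the result."""
    if whiteners is not None:
        W = [Ww @ V for Ww, V in zip(W_white, whiteners)]
    else:
        W = [Ww.copy() for Ww in W_white]
    Y = []
    for d, (Wd, Xd) in enumerate(zip(W, Xs)):
        Yd = Wd @ (Xd - Xd.mean(axis=1, keepdims=True))
        sd = Yd.std(axis=1)
        scale = 1.0 / np.maximum(sd, 1e-300)
        # sign convention: largest-magnitude sample positive
        peaks = Yd[np.arange(Yd.shape[0]), np.argmax(np.abs(Yd), axis=1)]
        scale *= np.where(peaks < 0, -1.0, 1.0)
        W[d] = scale[:, None] * Wd
        Y.append(W[d] @ Xd)
    return UnmixingResult(
        W=W,
        Y=Y,
        n_iterations=n_iter,
        converged=converged,
        algorithm=algorithm,
        cost_trace=np.asarray(trace),
    )


def _iva_optimize(X, prior: str, opts: AlgorithmOptions, algorithm: str) -> UnmixingResult:
    Xs = _as_arrays(X)
    D = len(Xs)
    K, L = Xs[0].shape
    if K < 2:
        raise ValueError("need at least two channels to separate")
    if any(x.shape != (K, L) for x in Xs):
        raise ValueError("all data sets must share one (K, L) shape")
    if L <= K:
        raise ValueError(f"need more samples than channels, got {K}x{L}")
    ridge = opts.scv_ridge
    if prior == "ggd":
        estimate_beta = opts.ggd_shape == "estimate"
        betas = None if estimate_beta else np.full(K, float(opts.ggd_shape))
    else:
        estimate_beta = False
        betas = None

    if opts.whiten:
        pairs = [whiten(x) for x in Xs]
        Z = [p[0] for p in pairs]
        whiteners = [p[1] for p in pairs]
    else:
        Z = [x - x.mean(axis=1, keepdims=True) for x in Xs]
        whiteners = None

    W = _init_unmixing(K, D, opts)
    S = _scv_stack([Wd @ Zd for Wd, Zd in zip(W, Z)])
    if estimate_beta:
        betas = _estimate_betas(S)
    cost = _cost_from_outputs(S, W, prior, betas, ridge)
    trace = [cost]
    step = opts.step_size
    converged = False
    n_iter = 0
    eye = np.eye(K)

    for n_iter in range(1, opts.max_iterations + 1):
        if estimate_beta and n_iter <= _BETA_UPDATE_ITERS:
            # shapes track the evolving outputs early on, then stay frozen
            # so the line-search objective is fixed
            betas = _estimate_betas(S)
            cost = _cost_from_outputs(S, W, prior, betas, ridge)
        score, _ = _prior_terms(S, prior, betas, ridge)
        # natural gradient: Delta W^d = (I - E[phi(y) y^T]) W^d.  Scales are
        # left free during optimisation (the cost handles them: it is
        # scale-invariant for the Gaussian/GGD priors and has a finite
        # scale optimum for the Laplacian); outputs are normalised to unit
        # variance only at finalisation.
        grads = []
        for d in range(D):
            M = score[:, d, :] @ S[:, d, :].T / L
            grads.append((eye - M) @ W[d])

        accepted = False
        trial_step = step
        for _ in range(30):
            W_new = [W[d] + trial_step * grads[d] for d in range(D)]
            S_new = _scv_stack([Wd @ Zd for Wd, Zd in zip(W_new, Z)])
            cost_new = _cost_from_outputs(S_new, W_new, prior, betas, ridge)
            if cost_new <= cost + 1e-12:
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            converged = True  # no descent direction at any usable step
            trace.append(cost)
            break
        delta = max(float(np.max(np.abs(Wn - Wo))) for Wn, Wo in zip(W_new, W))
        W, S, cost = W_new, S_new, cost_new
        trace.append(cost)
        # grow the step again after clean acceptances
        step = min(trial_step * 1.5, 2.0) if trial_step == step else trial_step
        if delta < opts.tolerance:
            converged = True
            break

    return _finalize(W, whiteners, Xs, n_iter, converged, algorithm, trace)


def iva_g(X, opts: AlgorithmOptions | None = None) -> UnmixingResult:
    """IVA with a multivariate Gaussian SCV prior (second-order only).

    Separation is driven purely by the covariance of each source across
    data sets, so sources must have distinct cross-data-set correlation
    profiles; i.i.d. Gaussian sources in a single data set are not
    identifiable.
    """
    return _iva_optimize(X, "gaussian", opts or AlgorithmOptions(), "iva_g")


def iva_l(X, opts: AlgorithmOptions | None = None) -> UnmixingResult:
    """IVA with a multivariate Laplacian SCV prior (higher-order only)."""
    return _iva_optimize(X, "laplacian", opts or AlgorithmOptions(), "iva_l")


def iva_ggd(X, opts: AlgorithmOptions | None = None) -> UnmixingResult:
    """IVA with a multivariate generalized Gaussian SCV prior.

    The shape ``opts.ggd_shape`` interpolates between Gaussian
    (``beta=1``) and Laplacian-like (``beta=0.5``) behaviour; the default
    ``"estimate"`` refits it each iteration from the marginal kurtosis of
    each SCV.
    """
    return _iva_optimize(X, "ggd", opts or AlgorithmOptions(), "iva_ggd")


def fastica(X, opts: AlgorithmOptions | None = None) -> UnmixingResult:
    """FastICA baseline (single data set, tanh contrast, symmetric mode)."""
    opts = opts or AlgorithmOptions()
    Xs = _as_arrays(X)
    if len(Xs) != 1:
        raise ValueError("fastica separates a single data set; got D > 1")
    Xd = Xs[0]
    K, L = Xd.shape
    if K < 2:
        raise ValueError("need at least two channels to separate")
    converged = True
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        ica = _SKFastICA(
            n_components=K,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=opts.max_iterations,
            tol=opts.tolerance,
            random_state=opts.seed,
        )
        try:
            ica.fit(Xd.T)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = _SKFastICA(
                    n_components=K,
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=opts.max_iterations,
                    tol=opts.tolerance,
                    random_state=opts.seed,
                )
                ica.fit(Xd.T)
    W = np.asarray(ica.components_, dtype=float)
    return _finalize([W], None, [Xd], int(ica.n_iter_), converged, "fastica", [])


def cca_bss(X, delay: int = 1) -> UnmixingResult:
    """Second-order separation from lagged covariance (CCA-style baseline).

    Canonical correlation between the recording and its ``delay``-sample
    shifted copy reduces, after whitening, to the eigendecomposition of
    the symmetrised lagged covariance.  Estimated sources come out
    mutually uncorrelated at lag 0 and ordered by decreasing
    lag-``delay`` autocorrelation; sources with identical autocorrelation
    (e.g. white noise) are not identifiable by this route.
    """
    Xs = _as_arrays(X)
    if len(Xs) != 1:
        raise ValueError("cca_bss separates a single data set; got D > 1")
    Xd = Xs[0]
    K, L = Xd.shape
    if delay < 1 or L <= delay + K:
        raise ValueError(f"need L > delay + K, got L={L}, delay={delay}, K={K}")
    Z, V = whiten(Xd)
    R = Z[:, delay:] @ Z[:, :-delay].T / (L - delay)
    Rs = 0.5 * (R + R.T)
    evals, evecs = eigh(Rs)
    order = np.argsort(evals)[::-1]  # decreasing lagged autocorrelation
    W_white = evecs[:, order].T
    return _finalize([W_white], [V], [Xd], 1, True, "cca", [])
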