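"""Batched Newton–Raphson maximum-likelihood logistic regression.

The phase->outcome analyses fit the same tiny logistic model (an intercept
plus sine/cosine regressors of a circular predictor) independently in tens of
thousands of (channel, time, frequency, subject) cells.  Fitting each cell
through a generic GLM front end dominates the runtime, so the solver below
runs plain Newton iterations vectorised over a leading batch axis.  It is
cross-checked against statsmodels' Binomial GLM and against a grid-search
ML oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

# A fitted |coefficient| beyond this is treated as (quasi-)separation: the
# likelihood is maximised at infinity and the MLE does not exist.
SEPARATION_BOUND = 15.0


def logistic(x: np.ndarray) -> np.ndarray:
    """Numerically stable sigmoid."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit logistic regressions by Newton–Raphson, batched.

    Parameters
    ----------
    X
        Design matrix, shape (n, k) or batched (..., n, k).
    y
        Binary responses in {0, 1}, shape (n,) or (..., n) broadcastable to X.
    max_iter, tol
        Newton iterations stop when the max absolute score falls below
        ``tol`` (per batch element) or after ``max_iter`` sweeps.
    ridge
        Tiny Tikhonov term added to the Hessian for numerical safety; it does
        not alter converged solutions to reported precision.

    Returns
    -------
    beta : (..., k) coefficient array
    converged : (...) boolean; False for non-convergence, ill-conditioned
        Hessians, separation (coefficients diverging), or one-class data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim < 2:
        raise ValueError("X must be at least (n, k)")
    single = X.ndim == 2
    if single:
        X = X[None]
    if y.ndim == X.ndim - 1:
        pass
    elif y.ndim == 1:
        y = np.broadcast_to(y, X.shape[:-2] + y.shape)
    else:
        raise ValueError("y shape incompatible with X")
    y = np.broadcast_to(y, X.shape[:-1])

    batch = X.shape[:-2]
    n, k = X.shape[-2:]
    Xf = X.reshape(-1, n, k)
    yf = np.ascontiguousarray(y.reshape(-1, n))
    b = Xf.shape[0]

    beta = np.zeros((b, k))
    ok = np.ones(b, dtype=bool)
    # one-class batches can never identify the model
    ybar = yf.mean(axis=1)
    ok &= (ybar > 0) & (ybar < 1)

    active = ok.copy()
    eye = np.eye(k)
    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        Xa = Xf[ia]
        eta = np.einsum("bnk,bk->bn", Xa, beta[ia])
        mu = logistic(eta)
        w = mu * (1.0 - mu)
        score = np.einsum("bnk,bn->bk", Xa, yf[ia] - mu)
        hess = np.einsum("bnk,bn,bnl->bkl", Xa, w, Xa) + ridge * eye
        try:
            step = np.linalg.solve(hess, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to per-element solves, flagging singular ones
            step = np.zeros_like(score)
            for j in range(len(ia)):
                try:
                    step[j] = np.linalg.solve(hess[j], score[j])
                except np.linalg.LinAlgError:
                    ok[ia[j]] = False
                    active[ia[j]] = False
        # cap the Newton step to keep early iterations stable
        norm = np.abs(step).max(axis=1, keepdims=True)
        step = np.where(norm > 5.0, step * (5.0 / np.maximum(norm, 5.0)),
                        step)
        beta[ia] += step
        done = np.abs(score).max(axis=1) < tol
        diverged = np.abs(beta[ia]).max(axis=1) > SEPARATION_BOUND
        ok[ia[diverged]] = False
        active[ia] = ~(done | diverged)
    ok &= ~active  # batches that never met tol are not converged
    ok &= np.isfinite(beta).all(axis=1)

    beta = beta.reshape(batch + (k,)) if not single else beta[0]
    ok = ok.reshape(batch) if not single else ok[0]
    return beta, ok


def circular_design(phase: np.ndarray) -> np.ndarray:
    """Design matrix [1, sin(phase), cos(phase)] along the last axis."""
    phase = np.asarray(phase, dtype=float)
    return np.stack(
        [np.ones_like(phase), np.sin(phase), np.cos(phase)], axis=-1
    )
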