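"""Independent oracles used to cross-check the package's implementations."""

from __future__ import annotations

import numpy as np


def grid_search_logit(phase: np.ndarray, y: np.ndarray,
                      n_refine: int = 8, span: float = 4.0,
                      n_pts: int = 13) -> np.ndarray:
    """Maximum-likelihood (beta0, beta1, beta2) by nested grid search.

    Exhaustively evaluates the Bernoulli log-likelihood of
    logistic(b0 + b1 sin(phase) + b2 cos(phase)) on a 3-D coefficient grid,
    then refines around the argmax.  Shares no code path with the Newton
    solver it checks.
    """
    S = np.column_stack([np.ones_like(phase), np.sin(phase), np.cos(phase)])
    y = np.asarray(y, dtype=float)
    center = np.zeros(3)
    for _ in range(n_refine):
        axes = [center[k] + np.linspace(-span, span, n_pts) for k in range(3)]
        G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        eta = G @ S.T
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        center = G[np.argmax(ll)]
        span *= 2.0 / (n_pts - 1)
    return center


def bh_mask_by_hand(pvals: np.ndarray, q: float) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up, written directly from the rule."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


def itc_direct(phases: np.ndarray) -> np.ndarray:
    """Inter-trial coherence from raw phase angles (trials on last axis)."""
    return np.abs(np.mean(np.exp(1j * phases), axis=-1))
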