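"""Group-level statistical machinery.

The second-level ("random effects") analysis treats each subject's fitted
(sin, cos) logistic coefficients as a bivariate observation — equivalently a
complex effect beta1 + i*beta2 — and tests the group mean against zero with
Hotelling's T-square.  The effect size is the *predictive value*, the
Euclidean norm of the group-mean coefficient vector, with a leave-one-subject-
out jackknife standard error.  Multiple testing over channel x time families
is controlled with Benjamini–Hochberg FDR, and condition contrasts use a
sign-flip style label permutation of the per-subject complex effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class SubjectBetas:
    """Per-subject logistic coefficients for one analysis cell.

    ``beta`` stacks (beta0, beta1, beta2); (beta1, beta2) is the complex
    phase effect.  ``converged`` is False when the fit failed (separation,
    one-class outcomes, too few trials) and the subject is excluded from
    group statistics.
    """

    beta: np.ndarray
    n_trials: int
    converged: bool

    @property
    def complex_effect(self) -> complex:
        return complex(self.beta[1], self.beta[2])


@dataclass
class GroupPhaseEffect:
    """Group summary of per-subject (beta1, beta2) effects in one cell."""

    mean_effect: np.ndarray      # (beta1_bar, beta2_bar)
    predictive_value: float
    se_jackknife: float
    t2: float
    p: float
    cov: np.ndarray
    n_subjects: int
    phi_opt: float               # nan when the mean effect is exactly zero


class SingularCovarianceError(np.linalg.LinAlgError):
    """Sample covariance of the subject effects is singular."""


def hotelling_t2(betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample Hotelling T² test of bivariate effects against zero.

    Parameters
    ----------
    betas
        Array (..., n_subjects, 2) of per-subject (beta1, beta2) pairs;
        leading axes are independent tests (e.g. channel x time cells).

    Returns
    -------
    t2, p
        T² = n m' S⁻¹ m with S the (n-1)-denominator sample covariance, and
        the p-value from the exact transformation
        F = ((n-2) / (2 (n-1))) T² on (2, n-2) degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim < 2 or betas.shape[-1] != 2:
        raise ValueError("betas must have shape (..., n, 2)")
    n = betas.shape[-2]
    if n < 3:
        raise ValueError("Hotelling test needs at least 3 subjects")
    m = betas.mean(axis=-2)
    c = betas - m[..., None, :]
    S = np.einsum("...ni,...nj->...ij", c, c) / (n - 1)
    det = S[..., 0, 0] * S[..., 1, 1] - S[..., 0, 1] * S[..., 1, 0]
    singular = np.abs(det) < 1e-300
    if np.any(singular):
        # a degenerate point mass at zero is the exact null: T2 = 0, p = 1
        zero_mean = np.all(m == 0, axis=-1)
        if np.any(singular & ~zero_mean):
            raise SingularCovarianceError(
                "sample covariance is singular (zero between-subject variance?)"
            )
        det = np.where(singular, 1.0, det)
    Sinv = np.empty_like(S)
    Sinv[..., 0, 0] = S[..., 1, 1]
    Sinv[..., 1, 1] = S[..., 0, 0]
    Sinv[..., 0, 1] = -S[..., 0, 1]
    Sinv[..., 1, 0] = -S[..., 1, 0]
    Sinv /= det[..., None, None]
    t2 = n * np.einsum("...i,...ij,...j->...", m, Sinv, m)
    f = (n - 2) / (2.0 * (n - 1)) * t2
    p = sstats.f.sf(f, 2, n - 2)
    if betas.ndim == 2:
        return float(t2), float(p)
    return t2, p


def predictive_value(betas: np.ndarray) -> tuple[float, float]:
    """Predictive value and optimal phase of a set of subject effects.

    PV = ||mean(beta1, beta2)||; the optimal phase is the angle phi
    maximising beta1_bar*sin(phi) + beta2_bar*cos(phi), i.e.
    atan2(beta1_bar, beta2_bar).  phi_opt is nan (flagged undefined) when
    the mean effect is exactly zero.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 1:
        betas = betas[None, :]
    m = betas.mean(axis=0)
    pv = float(np.hypot(m[0], m[1]))
    phi = float(np.arctan2(m[0], m[1])) if pv > 0 else float("nan")
    return pv, phi


def jackknife_se(
    values: np.ndarray,
    estimator: Callable[[np.ndarray], float] | None = None,
) -> float:
    """Leave-one-subject-out jackknife standard error of a group estimate.

    ``estimator`` maps an (n-1, ...) subject array to a scalar; by default it
    is the predictive value.  SE = sqrt((n-1)/n * sum_i (est_i - est_bar)^2).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least 2 subjects")
    if estimator is None:
        estimator = lambda b: predictive_value(b)[0]  # noqa: E731
    loo = np.array([
        estimator(np.delete(values, i, axis=0)) for i in range(n)
    ])
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask over a p-value family.

    The caller assembles the family (e.g. all channel x time cells); the
    returned boolean mask has the input's shape.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(pvals.shape, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = pvals.ravel()
    reject, *_ = multipletests(flat, alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)


def group_effect(betas: np.ndarray) -> GroupPhaseEffect:
    """Full group summary (PV, jackknife SE, T², p, phi_opt) for one cell."""
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    t2, p = hotelling_t2(betas)
    pv, phi = predictive_value(betas)
    se = jackknife_se(betas)
    m = betas.mean(axis=0)
    c = betas - m
    S = c.T @ c / (n - 1)
    return GroupPhaseEffect(
        mean_effect=m, predictive_value=pv, se_jackknife=se,
        t2=t2, p=p, cov=S, n_subjects=n, phi_opt=phi,
    )


def permute_condition_difference(
    betas_short: np.ndarray,
    betas_long: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation p-values for a condition difference in predictive value.

    Parameters
    ----------
    betas_short, betas_long
        Matched per-subject effects, shape (..., n_subjects, 2) with
        identical leading cell axes (e.g. channel x time).
    n_perm
        Number of label permutations; each permutation independently swaps
        each subject's short/long labels (the same swap pattern applied to
        every cell, preserving the spatial/temporal dependence).

    Returns
    -------
    p
        Per-cell p = (1 + #{perm : |ΔPV_perm| >= |ΔPV_obs|}) / (n_perm + 1);
        the observed statistic is included in the reference set, so the
        smallest attainable p is 1/(n_perm+1).  Apply :func:`fdr_bh` across
        the family afterwards.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    bs = np.asarray(betas_short, dtype=float)
    bl = np.asarray(betas_long, dtype=float)
    if bs.shape != bl.shape:
        raise ValueError("condition arrays must be matched in shape")
    n = bs.shape[-2]

    def pv(b):
        m = b.mean(axis=-2)
        return np.hypot(m[..., 0], m[..., 1])

    observed = np.abs(pv(bs) - pv(bl))
    count = np.zeros_like(observed)
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        s = np.where(swap[:, None], bl, bs)
        l = np.where(swap[:, None], bs, bl)
        stat = np.abs(pv(s) - pv(l))
        count += stat >= observed
    return (1.0 + count) / (n_perm + 1.0)
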