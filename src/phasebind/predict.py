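"""Phase extrapolation and the phase -> perceptual-outcome analysis.

The central question: does the instantaneous phase of a movement-locked
oscillation, estimated at a time t before movement onset and extrapolated to
the moment the stimulus appeared, predict the binary perceptual outcome?

Per subject, channel and phase-estimation time, the measured phase is
projected to the stimulus assuming a constant oscillation frequency f,

    phase_at_stim(t) = phase(t) + 2*pi*f*(t_stim - t),

and a logistic regression of the outcome on the sine and cosine of that
phase is fitted by maximum likelihood.  Group-level inference (Hotelling
T-square, predictive value, jackknife SE, optimal phase, BH-FDR across
channels x times) is delegated to :mod:`phasebind.inference`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from ._logistic import circular_design, fit_logit, logistic
from .io import filter_trials
from .simulate import wrap_phase
from .spectral import AnalyticEpochs

DEFAULT_TIMES = np.arange(-1.9, 0.0 + 1e-9, 0.025)
MIN_TRIALS_DEFAULT = 30


def extrapolate_phase(
    phase: np.ndarray, f: float, t: np.ndarray, t_stim: np.ndarray
) -> np.ndarray:
    """Project a phase measured at time ``t`` to the stimulus time.

    Assumes a constant frequency ``f`` (Hz): the returned angle is
    ``phase + 2*pi*f*(t_stim - t)`` wrapped to (-pi, pi].  Works forward
    (t_stim > t) and backward (t_stim < t).
    """
    return wrap_phase(
        np.asarray(phase) + 2 * np.pi * f * (np.asarray(t_stim) - np.asarray(t))
    )


class PhaseOutcomeLogistic:
    """Logistic regression of a binary outcome on a circular predictor.

    Fits P(Y=1 | phi) = logistic(beta0 + beta1*sin(phi) + beta2*cos(phi))
    by maximum likelihood.  (beta1, beta2) is the complex phase effect; its
    norm kappa = |beta1 + i*beta2| measures the phase's leverage on the
    outcome and atan2(beta1, beta2) the phase of maximal success
    probability.

    Parameters
    ----------
    min_trials : int
        Minimum number of trials (with both outcome classes present)
        required to attempt a fit.

    Attributes (after ``fit``)
    --------------------------
    beta_ : (3,) array of (beta0, beta1, beta2)
    converged_ : bool, False on separation/non-convergence/too few trials
    n_trials_ : int
    """

    def __init__(self, min_trials: int = MIN_TRIALS_DEFAULT):
        self.min_trials = min_trials

    def get_params(self, deep: bool = True) -> dict:
        return {"min_trials": self.min_trials}

    def set_params(self, **params) -> "PhaseOutcomeLogistic":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, phase: np.ndarray, y: np.ndarray) -> "PhaseOutcomeLogistic":
        phase = np.asarray(phase, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if phase.shape != y.shape:
            raise ValueError("phase and y must have the same length")
        self.n_trials_ = phase.size
        if phase.size < self.min_trials or len(np.unique(y)) < 2:
            self.beta_ = np.full(3, np.nan)
            self.converged_ = False
            return self
        beta, ok = fit_logit(circular_design(phase), y)
        self.beta_ = beta
        self.converged_ = bool(ok)
        return self

    def predict_proba(self, phase: np.ndarray) -> np.ndarray:
        """P(Y=1) per trial as an (n, 2) array of [P(0), P(1)]."""
        eta = circular_design(np.asarray(phase, dtype=float)) @ self.beta_
        p1 = logistic(eta)
        return np.column_stack([1 - p1, p1])

    def predict(self, phase: np.ndarray) -> np.ndarray:
        return (self.predict_proba(phase)[:, 1] >= 0.5).astype(int)

    @property
    def complex_effect_(self) -> complex:
        return complex(self.beta_[1], self.beta_[2])


def fit_phase_outcome_model(
    phase_at_stim: np.ndarray,
    outcomes: np.ndarray,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> inference.SubjectBetas:
    """One subject's ML fit of the phase->outcome model for one cell."""
    est = PhaseOutcomeLogistic(min_trials=min_trials).fit(phase_at_stim, outcomes)
    return inference.SubjectBetas(
        beta=est.beta_, n_trials=est.n_trials_, converged=est.converged_
    )


@dataclass
class PhasePredictMap:
    """Group predictive-value map over channels x phase-estimation times."""

    times: np.ndarray
    channel_labels: list[str]
    pv: np.ndarray            # (n_ch, n_times) predictive value
    se: np.ndarray            # jackknife SE of pv
    t2: np.ndarray
    p: np.ndarray
    phi_opt: np.ndarray
    n_subjects: np.ndarray    # converged subjects per cell
    mean_trials: np.ndarray   # mean trials per subject per cell
    significant: np.ndarray   # BH-FDR mask over the channel x time family
    variant: str
    freq: float
    betas: np.ndarray = field(repr=False, default=None)      # (n_subj, ch, t, 3)
    converged: np.ndarray = field(repr=False, default=None)  # (n_subj, ch, t)

    @property
    def significant_times(self) -> np.ndarray:
        """Times at which at least one channel survives FDR correction."""
        return self.times[self.significant.any(axis=0)]


def _subject_cell_fits(
    analytic: AnalyticEpochs,
    trials: pd.DataFrame,
    times: np.ndarray,
    variant: str,
    freq: float,
    min_trials: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the phase->outcome model in every (channel, time) cell.

    Returns (betas (ch, t, 3), converged (ch, t), n_used (t,)).
    """
    n_ch = analytic.values.shape[0]
    n_t = times.size
    t_stim = trials["t_stim"].to_numpy(dtype=float)
    y = trials["outcome"].to_numpy(dtype=float)
    idx = np.array([analytic.sample_index(t) for t in times])
    phases = np.angle(analytic.values[:, idx, :])  # (ch, n_t, n_trials)

    betas = np.full((n_ch, n_t, 3), np.nan)
    conv = np.zeros((n_ch, n_t), dtype=bool)
    n_used = np.zeros(n_t, dtype=int)

    if variant in ("all_trials", "stimulus_locked"):
        if variant == "all_trials":
            ph = extrapolate_phase(phases, freq, times[None, :, None],
                                   t_stim[None, None, :])
        else:
            ph = phases  # phase at time t relative to stimulus; no projection
        n_used[:] = t_stim.size
        if t_stim.size >= min_trials and 0 < y.mean() < 1:
            X = circular_design(ph)
            b, ok = fit_logit(X, y)
            betas, conv = b, ok
    elif variant == "forward_only":
        for ti, t in enumerate(times):
            keep = t_stim > t
            n_used[ti] = int(keep.sum())
            if n_used[ti] < min_trials or len(np.unique(y[keep])) < 2:
                continue
            ph = extrapolate_phase(phases[:, ti, keep], freq, t, t_stim[keep])
            b, ok = fit_logit(circular_design(ph), y[keep])
            betas[:, ti], conv[:, ti] = b, ok
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return betas, conv, n_used


def predict_timecourse(
    analytic_by_subject: list[AnalyticEpochs],
    trials_by_subject: list[pd.DataFrame],
    times: np.ndarray | None = None,
    variant: str = "all_trials",
    freq: float | None = None,
    q: float = 0.05,
    min_trials: int = MIN_TRIALS_DEFAULT,
    fdr_family: str = "space_time",
) -> PhasePredictMap:
    """Group predictive-value map of extrapolated phase for the outcome.

    Parameters
    ----------
    analytic_by_subject, trials_by_subject
        Matched per-subject analytic epochs and trial tables; trial-table
        rows correspond positionally to the epoch trial axis.  Trials are
        restricted to the |t_stim| <= 0.6 s analysis window internally.
    times
        Phase-estimation times (s); default -1.9..0 in steps of 0.025.
        For the ``stimulus_locked`` variant these are times relative to
        stimulus onset (paper interval [-0.65, 0]).
    variant
        ``all_trials``, ``forward_only`` (only trials whose stimulus follows
        the estimation time) or ``stimulus_locked`` (no extrapolation;
        epochs must be stimulus-aligned).
    freq
        Extrapolation frequency in Hz; defaults to the analytic container's
        center frequency.
    fdr_family
        ``"space_time"`` corrects across all channels and times;
        ``"space"`` corrects each time separately across channels (used for
        the single-time control variants).
    """
    if len(analytic_by_subject) != len(trials_by_subject):
        raise ValueError("per-subject lists must be matched")
    if times is None:
        times = DEFAULT_TIMES if variant != "stimulus_locked" else \
            np.arange(-0.65, 0.0 + 1e-9, 0.025)
    times = np.asarray(times, dtype=float)
    if freq is None:
        freq = analytic_by_subject[0].center_freq
    n_subj = len(analytic_by_subject)
    labels = analytic_by_subject[0].channel_labels
    n_ch = len(labels)
    n_t = times.size

    betas = np.full((n_subj, n_ch, n_t, 3), np.nan)
    conv = np.zeros((n_subj, n_ch, n_t), dtype=bool)
    trial_counts = np.zeros((n_subj, n_t))
    for si, (an, tr) in enumerate(zip(analytic_by_subject, trials_by_subject)):
        if an.values.shape[0] != n_ch:
            raise ValueError("channel counts differ across subjects")
        if len(tr) != an.values.shape[2]:
            raise ValueError(
                f"subject {si}: trial table rows ({len(tr)}) do not match "
                f"epoch trials ({an.values.shape[2]})"
            )
        mask = filter_trials(tr.reset_index(drop=True), "analysis_window").index
        an_cut = AnalyticEpochs(
            values=an.values[:, :, np.asarray(mask)], fs_out=an.fs_out,
            time=an.time, center_freq=an.center_freq, band=an.band,
            channel_labels=an.channel_labels, alignment=an.alignment,
        )
        tr_cut = tr.reset_index(drop=True).loc[mask]
        b, ok, n_used = _subject_cell_fits(
            an_cut, tr_cut, times, variant, freq, min_trials)
        betas[si], conv[si], trial_counts[si] = b, ok, n_used

    pv = np.full((n_ch, n_t), np.nan)
    se = np.full((n_ch, n_t), np.nan)
    t2 = np.full((n_ch, n_t), np.nan)
    p = np.full((n_ch, n_t), np.nan)
    phi = np.full((n_ch, n_t), np.nan)
    n_ok = conv.sum(axis=0)
    masked_cells = 0
    for c in range(n_ch):
        for ti in range(n_t):
            ok = conv[:, c, ti]
            if ok.sum() < 3:
                masked_cells += 1
                continue
            g = inference.group_effect(betas[ok, c, ti, 1:])
            pv[c, ti], se[c, ti] = g.predictive_value, g.se_jackknife
            t2[c, ti], p[c, ti], phi[c, ti] = g.t2, g.p, g.phi_opt
    if masked_cells:
        warnings.warn(
            f"{masked_cells} cell(s) had fewer than 3 converged subjects "
            "and were masked"
        )

    sig = np.zeros_like(p, dtype=bool)
    valid = np.isfinite(p)
    if fdr_family == "space_time":
        if valid.any():
            sig[valid] = inference.fdr_bh(p[valid], q=q)
    elif fdr_family == "space":
        for ti in range(n_t):
            col = valid[:, ti]
            if col.any():
                sig[col, ti] = inference.fdr_bh(p[col, ti], q=q)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")

    return PhasePredictMap(
        times=times, channel_labels=list(labels), pv=pv, se=se, t2=t2, p=p,
        phi_opt=phi, n_subjects=n_ok, mean_trials=trial_counts.mean(axis=0),
        significant=sig, variant=variant, freq=float(freq),
        betas=betas, converged=conv,
    )


def predict_frequency_sweep(
    epochs_by_subject: list,
    trials_by_subject: list[pd.DataFrame],
    grid: list[tuple[float, tuple[float, float]]] | None = None,
    times: np.ndarray | None = None,
    window: tuple[float, float] = (-1.9, 0.0),
    **kwargs,
) -> list[PhasePredictMap]:
    """Frequency-resolved predictive-value maps.

    For each (center, band) of ``grid`` (default the 3.5–15.5 Hz sliding
    grid), the raw epochs are band-passed to ``band`` and the analysis of
    :func:`predict_timecourse` is run with the extrapolation frequency set
    to the band's center.  Returns one map per grid entry.
    """
    from .spectral import bandpass_analytic, frequency_grid

    if grid is None:
        grid = frequency_grid()
    maps = []
    for center, band in grid:
        analytic = [bandpass_analytic(ep, band=band, window=window)
                    for ep in epochs_by_subject]
        maps.append(predict_timecourse(analytic, trials_by_subject,
                                       times=times, freq=center, **kwargs))
    return maps


def joint_early_late_model(
    phase_early: np.ndarray,
    phase_late: np.ndarray,
    outcomes: np.ndarray,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> dict:
    """Joint logistic fit with early and late phases as partialled predictors.

    Design: intercept + sin/cos of the early phase + sin/cos of the late
    phase, fitted in one model, so each pair of coefficients reflects the
    corresponding phase's contribution with the other partialled out.

    Returns a dict with keys ``beta`` (5,), ``early``/``late`` (each a
    (beta_sin, beta_cos) pair), ``converged`` and ``collinear``.  Perfectly
    coupled phases (late = early + const) make the design rank-deficient;
    such fits are flagged ``collinear`` and not converged.
    """
    e = np.asarray(phase_early, dtype=float).ravel()
    l = np.asarray(phase_late, dtype=float).ravel()
    y = np.asarray(outcomes, dtype=float).ravel()
    if not (e.shape == l.shape == y.shape):
        raise ValueError("phase and outcome arrays must be matched")
    X = np.column_stack([
        np.ones_like(e), np.sin(e), np.cos(e), np.sin(l), np.cos(l)])
    out = {"beta": np.full(5, np.nan), "early": np.full(2, np.nan),
           "late": np.full(2, np.nan), "converged": False, "collinear": False}
    if e.size < min_trials or len(np.unique(y)) < 2:
        return out
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        out["collinear"] = True
        return out
    beta, ok = fit_logit(X, y)
    out["beta"] = beta
    out["early"] = beta[1:3]
    out["late"] = beta[3:5]
    out["converged"] = bool(ok)
    return out
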