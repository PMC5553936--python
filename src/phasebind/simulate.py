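"""Ground-truth synthetic data: trial tables, force traces and EEG epochs.

The generator emulates the statistical structure the downstream analyses
assume, with known parameters so that recovery can be tested end to end:

* movement times drawn per condition around the instructed interval
  (short 1.5 s, long 2.3 s from cue offset), truncated positive;
* stimulus times uniform in a jitter window around the instructed movement
  time, re-expressed relative to the *produced* movement onset;
* EEG epochs = 1/f Gaussian background plus movement-locked theta bursts
  cos(2*pi*f*t + theta0) under configurable envelopes, so the oscillation's
  phase at movement onset (t = 0) is theta0 — the same convention the phase
  measurement and extrapolation modules use;
* binary outcomes Bernoulli(logistic(beta0 + kappa*cos(phi - phi_opt)))
  where phi is the oscillation's latent phase at stimulus time.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logistic import logistic
from .io import EpochSet, ForceTrace


@dataclass
class BurstSpec:
    """A movement-locked oscillatory burst with a Gaussian envelope.

    ``center``/``width`` in seconds (width = Gaussian SD), ``amplitude`` in
    signal units, ``phase_jitter_sd`` in radians of extra per-trial phase
    noise applied to this burst only (0 = perfectly movement-locked).
    """

    center: float
    width: float = 0.15
    amplitude: float = 1.0
    phase_jitter_sd: float = 0.0


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment.

    Defaults mirror the study design: two instructed movement intervals
    (1.5 s / 2.3 s) with empirical onset-time SDs of 0.2 / 0.24 s, stimulus
    jitter uniform in [-0.35, +0.25] s around the instructed time, a 4 Hz
    movement-locked rhythm with an early (-1.4 s) and a late (-0.05 s)
    burst, and a phase->outcome logistic model around 75% correct.
    """

    n_subjects: int = 17
    n_trials: int = 400
    conditions: dict = field(default_factory=lambda: {
        "short": (1.5, 0.2), "long": (2.3, 0.24)})
    stim_jitter: tuple[float, float] = (-0.35, 0.25)
    n_channels: int = 8
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-2.9, 1.0)
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    theta_freq: float = 4.0
    bursts: list[BurstSpec] = field(default_factory=lambda: [
        BurstSpec(center=-1.4), BurstSpec(center=-0.05)])
    theta0: float = 0.0
    theta0_subject_sd: float = 0.0
    beta0: float = 1.0986122886681098  # logit(0.75)
    kappa: float = 0.8
    phi_opt: float = np.pi / 3

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.stim_jitter[1] <= self.stim_jitter[0]:
            raise ValueError("stim_jitter interval must be non-empty")
        if self.fs <= 2 * self.theta_freq:
            raise ValueError("fs must exceed twice the theta frequency")
        if any(b.amplitude < 0 for b in self.bursts):
            raise ValueError("burst amplitudes must be non-negative")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) + np.pi


def simulate_trials(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "s01",
    theta0: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw one subject's trial table and the latent phase at stimulus.

    Movement time ~ Normal(instructed, SD) truncated to be positive; the
    stimulus time is uniform in ``stim_jitter`` around the *instructed*
    movement time and is returned relative to the produced movement onset
    (column ``t_stim``).  The latent oscillation phase at the stimulus is
    theta0 + 2*pi*f*t_stim, wrapped.

    Returns (trial table, latent phase array); outcomes are filled in by
    :func:`simulate_outcomes` on the latent phases.
    """
    rng = np.random.default_rng(rng)
    if theta0 is None:
        theta0 = config.theta0
    conds = rng.permutation(
        np.repeat(list(config.conditions), -(-config.n_trials // len(config.conditions)))
    )[: config.n_trials]
    mean = np.array([config.conditions[c][0] for c in conds])
    sd = np.array([config.conditions[c][1] for c in conds])
    t_move = mean + sd * rng.standard_normal(config.n_trials)
    bad = t_move <= 0
    while bad.any():  # truncate the Normal at zero by redrawing
        t_move[bad] = mean[bad] + sd[bad] * rng.standard_normal(bad.sum())
        bad = t_move <= 0
    jit = rng.uniform(*config.stim_jitter, size=config.n_trials)
    # stimulus at instructed + jitter (from cue offset) -> relative to onset
    t_stim = (mean + jit) - t_move
    phase = wrap_phase(theta0 + 2 * np.pi * config.theta_freq * t_stim)
    trials = pd.DataFrame({
        "subject_id": subject_id,
        "trial_id": np.arange(config.n_trials),
        "condition": conds,
        "t_move": t_move,
        "t_stim": t_stim,
        "outcome": 0,
    })
    return trials, phase


def simulate_outcomes(
    phase_at_stim: np.ndarray,
    beta0: float,
    kappa: float,
    phi_opt: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw binary outcomes from the phase->outcome logistic model.

    P(correct) = logistic(beta0 + kappa * cos(phi - phi_opt)); equivalently
    the sine/cosine parameterisation with beta1 = kappa*sin(phi_opt),
    beta2 = kappa*cos(phi_opt).  Success probability is maximal at
    phi = phi_opt.
    """
    if not (np.isfinite(beta0) and np.isfinite(kappa) and np.isfinite(phi_opt)):
        raise ValueError("parameters must be finite")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(rng)
    phi = np.asarray(phase_at_stim, dtype=float)
    eta = beta0 + kappa * np.cos(phi - phi_opt)
    p = logistic(np.atleast_1d(eta)).reshape(np.shape(eta))
    return (rng.random(phi.shape) < p).astype(int)


def one_over_f_noise(
    shape: tuple[int, ...],
    fs: float,
    exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum (unit RMS).

    Synthesised by spectrally shaping white Gaussian noise along the last
    axis; the DC bin is zeroed.
    """
    rng = np.random.default_rng(rng)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    rms = np.sqrt(np.mean(shaped ** 2, axis=-1, keepdims=True))
    return shaped / np.maximum(rms, 1e-30)


def simulate_eeg(
    trials: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    theta0: float | None = None,
) -> tuple[EpochSet, list[ForceTrace]]:
    """Generate movement-aligned epochs plus a force trace per trial.

    Each epoch is 1/f background noise plus the sum of the configured theta
    bursts, envelope(t) * cos(2*pi*f*t + theta0 [+ per-burst jitter]); the
    phase convention matches :func:`simulate_trials`, so phases measured from
    these epochs and extrapolated to the stimulus agree with the latent
    outcome-generating phases up to noise.

    Force traces are flat during holding and rise quadratically from the
    movement-onset sample, satisfying the 15-consecutive-positive-difference
    detection rule exactly at the configured onset.
    """
    rng = np.random.default_rng(rng)
    if theta0 is None:
        theta0 = config.theta0
    n_trials = len(trials)
    t0, t1 = config.epoch_window
    n_samp = int(round((t1 - t0) * config.fs)) + 1
    time = t0 + np.arange(n_samp) / config.fs
    nch = config.n_channels

    data = config.noise_amplitude * one_over_f_noise(
        (nch, n_trials, n_samp), config.fs, config.noise_exponent, rng
    )
    for burst in config.bursts:
        env = burst.amplitude * np.exp(
            -0.5 * ((time - burst.center) / burst.width) ** 2
        )
        jitter = (
            burst.phase_jitter_sd * rng.standard_normal(n_trials)
            if burst.phase_jitter_sd > 0 else np.zeros(n_trials)
        )
        osc = np.cos(
            2 * np.pi * config.theta_freq * time[None, :]
            + theta0 + jitter[:, None]
        )
        data += env[None, :] * osc[None, :, :]
    epochs = EpochSet(
        data=np.transpose(data, (0, 2, 1)),
        fs=config.fs,
        time=time,
        channel_labels=[f"ch{i:02d}" for i in range(nch)],
        channel_pos=_ring_positions(nch),
        alignment="movement",
    )

    force_fs = 1000.0
    onset_idx = int(round(2.0 * force_fs))  # onset 2 s into each trace
    n_force = onset_idx + 500
    ramp = np.zeros(n_force)
    after = np.arange(n_force - onset_idx, dtype=float) / force_fs
    ramp[onset_idx:] = after ** 2 * 40.0
    traces = [ForceTrace(samples=ramp.copy(), fs=force_fs)
              for _ in range(n_trials)]
    return epochs, traces


def _ring_positions(n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([np.cos(ang), np.sin(ang)])


def simulate_dataset(
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> list[dict]:
    """Simulate the full multi-subject experiment.

    Returns one dict per subject with keys ``trials`` (outcome column
    filled), ``phase`` (latent phase at stimulus), ``epochs``, ``forces``
    and ``theta0`` (the subject's movement-locked phase).
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(config.n_subjects):
        theta0 = config.theta0 + (
            config.theta0_subject_sd * rng.standard_normal()
            if config.theta0_subject_sd > 0 else 0.0
        )
        sid = f"s{s + 1:02d}"
        trials, phase = simulate_trials(config, rng, subject_id=sid,
                                        theta0=theta0)
        trials["outcome"] = simulate_outcomes(
            phase, config.beta0, config.kappa, config.phi_opt, rng
        )
        epochs, forces = simulate_eeg(trials, config, rng, theta0=theta0)
        subjects.append({
            "subject_id": sid, "trials": trials, "phase": phase,
            "epochs": epochs, "forces": forces, "theta0": theta0,
        })
    return subjects
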