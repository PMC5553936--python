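"""Narrow-band analytic signals, frequency sweeps, and normalized power.

Instantaneous phase is estimated by zero-phase band-pass filtering
(two-pass Butterworth, default 3–5 Hz, 3rd order per pass) followed by the
Hilbert transform; the complex analytic signal is then resampled to a common
output rate (default 200 Hz).  Complex values — not just phase angles — are
retained so amplitude-weighted statistics (non-normalized mean resultant
vectors) remain computable downstream.

Filtering and the Hilbert transform are applied to the longest available
epoch before any cutting, so edge artifacts fall outside the analysis
window.  Phase convention: cosine phase (0 at a signal peak), wrapped to
(-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as ssignal

from .io import EpochSet


@dataclass
class AnalyticEpochs:
    """Complex analytic signal per channel x sample x trial.

    ``values[c, s, i]`` is the analytic signal of channel c, trial i at
    ``time[s]`` (seconds relative to the alignment event); its argument is
    the instantaneous phase, its modulus the instantaneous amplitude.
    """

    values: np.ndarray
    fs_out: float
    time: np.ndarray
    center_freq: float
    band: tuple[float, float]
    channel_labels: list[str]
    alignment: str = "movement"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be channels x samples x trials")
        if self.time.shape[0] != self.values.shape[1]:
            raise ValueError("time axis does not match sample dimension")
        if not (self.band[0] < self.center_freq < self.band[1]):
            raise ValueError("band must straddle the center frequency")
        if not np.all(np.isfinite(np.abs(self.values))):
            raise ValueError("analytic values must be finite")

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def sample_index(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (must be on the grid)."""
        i = int(np.argmin(np.abs(self.time - t)))
        if abs(self.time[i] - t) > 0.5 / self.fs_out + 1e-9:
            raise ValueError(f"time {t} s outside the analytic window")
        return i


def bandpass_analytic(
    epochs: EpochSet,
    band: tuple[float, float] = (3.0, 5.0),
    order: int = 3,
    fs_out: float = 200.0,
    window: tuple[float, float] | None = None,
) -> AnalyticEpochs:
    """Band-pass filter epochs and return the resampled analytic signal.

    Parameters
    ----------
    epochs
        Real-valued epochs; filtering uses the full epoch extent.
    band
        Pass band (lo, hi) in Hz; must lie strictly inside (0, fs/2).
    order
        Butterworth order per pass (two passes via filtfilt -> zero phase).
    fs_out
        Output sampling rate of the complex analytic signal.
    window
        Optional (t_lo, t_hi) in seconds; the result is cut to this window
        *after* filtering and Hilbert transform, keeping edge artifacts out.
    """
    lo, hi = band
    nyq = epochs.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    n_samp = epochs.data.shape[1]
    min_len = int(6 * epochs.fs / lo)
    if n_samp < min_len:
        raise ValueError(
            f"epoch too short for stable filtering at {lo} Hz: "
            f"{n_samp} samples, need >= {min_len} (about {min_len / epochs.fs:.1f} s)"
        )
    sos = ssignal.butter(order, [lo, hi], btype="bandpass",
                         fs=epochs.fs, output="sos")
    filtered = ssignal.sosfiltfilt(sos, epochs.data, axis=1)
    analytic = ssignal.hilbert(filtered, axis=1)

    frac = Fraction(fs_out / epochs.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if (up, down) != (1, 1):
        re = ssignal.resample_poly(analytic.real, up, down, axis=1)
        im = ssignal.resample_poly(analytic.imag, up, down, axis=1)
        analytic = re + 1j * im
    n_out = analytic.shape[1]
    time = epochs.time[0] + np.arange(n_out) / fs_out

    out = AnalyticEpochs(
        values=analytic, fs_out=fs_out, time=time,
        center_freq=0.5 * (lo + hi), band=(lo, hi),
        channel_labels=list(epochs.channel_labels),
        alignment=epochs.alignment,
    )
    if window is not None:
        out = cut_window(out, window)
    return out


def cut_window(analytic: AnalyticEpochs, window: tuple[float, float]) -> AnalyticEpochs:
    """Cut an analytic container to the closed time window (seconds)."""
    lo, hi = window
    keep = (analytic.time >= lo - 1e-9) & (analytic.time <= hi + 1e-9)
    if not keep.any():
        raise ValueError("window outside the analytic time range")
    return AnalyticEpochs(
        values=analytic.values[:, keep, :],
        fs_out=analytic.fs_out,
        time=analytic.time[keep],
        center_freq=analytic.center_freq,
        band=analytic.band,
        channel_labels=analytic.channel_labels,
        alignment=analytic.alignment,
    )


def frequency_grid(
    lo: float = 3.5, hi: float = 15.5, step: float = 0.5, width: float = 2.0
) -> list[tuple[float, tuple[float, float]]]:
    """Sliding-window frequency grid: (center, (center-w/2, center+w/2)).

    Centers run from ``lo`` to ``hi`` inclusive in steps of ``step``; when
    ``step`` does not divide (hi - lo) the grid is truncated below ``hi``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    centers = lo + step * np.arange(n)
    return [(float(c), (float(c - width / 2), float(c + width / 2)))
            for c in centers]


def tf_power(
    epochs: EpochSet,
    grid: list[tuple[float, tuple[float, float]]] | None = None,
    fs_out: float = 200.0,
    window: tuple[float, float] = (-1.9, 0.0),
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged band power over time, normalized per frequency row.

    For each (center, band) of ``grid`` the squared analytic amplitude is
    averaged over trials and channels, cut to ``window`` and divided by its
    own mean over the window, so every frequency row averages to 1.

    Returns (centers, time, power) with power of shape (n_freqs, n_times).
    """
    if epochs.n_trials == 0:
        raise ValueError("tf_power requires at least one trial")
    if grid is None:
        grid = frequency_grid()
    rows = []
    time = None
    for center, band in grid:
        an = bandpass_analytic(epochs, band=band, order=order,
                               fs_out=fs_out, window=window)
        p = np.mean(np.abs(an.values) ** 2, axis=(0, 2))
        rows.append(p / p.mean())
        time = an.time
    centers = np.array([c for c, _ in grid])
    return centers, time, np.array(rows)
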