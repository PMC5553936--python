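"""Spectral analysis of movement-aligned perceptual performance.

Two complementary tests for rhythmicity in the probability of a correct
response as a function of stimulus time relative to movement onset:

* a random-effects analysis fitting, per subject and frequency, a logistic
  regression of the outcome on sin(2*pi*f*t_stim) and cos(2*pi*f*t_stim),
  with a group-level Hotelling T-square on the (sin, cos) coefficients;
* a fixed-effects analysis binning the pooled percent-correct time course
  (bin 0.05 s, step 0.025 s), Hanning-tapering, Fourier transforming, and
  comparing the observed power per frequency against surrogates obtained by
  permuting the pairing of stimulus times and outcomes.

The binned series is demeaned before tapering so a constant performance
level carries no power at any analysis frequency; the tapered series is
zero-padded to evaluate the spectrum on a 0.5 Hz grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import inference
from ._logistic import fit_logit

DEFAULT_FREQS = np.arange(2.5, 14.5 + 1e-9, 0.5)


def bin_performance(
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.575, 0.475),
    binwidth: float = 0.05,
    step: float = 0.025,
    min_per_bin: int = 5,
) -> pd.DataFrame:
    """Sliding-window percent correct versus stimulus time.

    Bins are half-open intervals [left, left+binwidth) with lefts stepping
    by ``step`` from ``window[0]``; each interior trial therefore falls in
    exactly binwidth/step bins.  Columns: ``t`` (bin center), ``n``,
    ``pct_correct`` (nan for empty bins) and ``thin`` (n < min_per_bin).
    """
    t = trials["t_stim"].to_numpy(dtype=float)
    y = trials["outcome"].to_numpy(dtype=float)
    lo, hi = window
    n_bins = int(np.floor((hi - lo - binwidth) / step + 1e-9)) + 1
    lefts = lo + step * np.arange(n_bins)
    centers = lefts + binwidth / 2
    n = np.zeros(n_bins, dtype=int)
    pct = np.full(n_bins, np.nan)
    for b, left in enumerate(lefts):
        m = (t >= left - 1e-12) & (t < left + binwidth - 1e-12)
        n[b] = m.sum()
        if n[b]:
            pct[b] = 100.0 * y[m].mean()
    if not n.any():
        raise ValueError("no trials fall in any bin")
    return pd.DataFrame({
        "t": centers, "n": n, "pct_correct": pct,
        "thin": n < min_per_bin,
    })


def behavior_spectrum_random_effects(
    trials: pd.DataFrame,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> pd.DataFrame:
    """Random-effects phase-regression spectrum of perceptual performance.

    For each subject and frequency, a logistic regression of the outcome on
    a sine and cosine of 2*pi*f*t_stim is fitted by maximum likelihood; per
    frequency, the per-subject (sin, cos) coefficients are submitted to the
    group Hotelling T-square against zero.  p-values are uncorrected across
    frequencies.

    Returns a frame with columns ``freq, pv, se_jackknife, t2, p,
    n_subjects, phi_opt``; per-subject coefficients are attached as
    ``result.attrs["betas"]`` (n_subjects, n_freqs, 3) with the convergence
    mask in ``result.attrs["converged"]``.
    """
    freqs = np.asarray(freqs, dtype=float)
    subjects = list(trials["subject_id"].unique())
    n_f = freqs.size
    betas = np.full((len(subjects), n_f, 3), np.nan)
    conv = np.zeros((len(subjects), n_f), dtype=bool)
    for si, sid in enumerate(subjects):
        sub = trials.loc[trials["subject_id"] == sid]
        t = sub["t_stim"].to_numpy(dtype=float)
        y = sub["outcome"].to_numpy(dtype=float)
        arg = 2 * np.pi * freqs[:, None] * t[None, :]
        X = np.stack([np.ones_like(arg), np.sin(arg), np.cos(arg)], axis=-1)
        b, ok = fit_logit(X, y)
        betas[si], conv[si] = b, ok

    rows = []
    for fi, f in enumerate(freqs):
        ok = conv[:, fi]
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} subject fit(s) did not converge at "
                f"{f} Hz; excluded from group statistics"
            )
        b = betas[ok, fi, 1:]
        if b.shape[0] >= 3:
            t2, p = inference.hotelling_t2(b)
            pv, phi = inference.predictive_value(b)
            se = inference.jackknife_se(b)
        else:
            t2 = p = pv = se = phi = np.nan
        rows.append((f, pv, se, t2, p, int(ok.sum()), phi))
    out = pd.DataFrame(rows, columns=[
        "freq", "pv", "se_jackknife", "t2", "p", "n_subjects", "phi_opt"])
    out.attrs["betas"] = betas
    out.attrs["converged"] = conv
    return out


def _taper_and_power(series: np.ndarray, step: float, freqs: np.ndarray,
                     n_pad: int) -> np.ndarray:
    """Demean, Hanning-taper, zero-pad, FFT; power at the requested freqs."""
    x = series - series.mean(axis=0, keepdims=True)
    w = np.hanning(x.shape[0])
    x = x * (w[:, None] if x.ndim == 2 else w)
    spec = np.fft.rfft(x, n=n_pad, axis=0)
    fft_freqs = np.fft.rfftfreq(n_pad, d=step)
    idx = np.array([int(np.argmin(np.abs(fft_freqs - f))) for f in freqs])
    if np.abs(fft_freqs[idx] - freqs).max() > 1e-6:
        raise ValueError("padded FFT grid does not contain requested freqs")
    return np.abs(spec[idx]) ** 2


def behavior_spectrum_fft_permutation(
    trials: pd.DataFrame,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    freqs: np.ndarray = DEFAULT_FREQS,
    window: tuple[float, float] = (-0.575, 0.475),
    binwidth: float = 0.05,
    step: float = 0.025,
    min_per_bin: int = 5,
    q: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effects FFT spectrum with a trial-level permutation test.

    The pooled trials are binned (:func:`bin_performance`), thin bins
    (fewer than ``min_per_bin`` trials) are linearly interpolated from their
    neighbours, and the demeaned, Hanning-tapered series is zero-padded and
    Fourier transformed.  Surrogates permute the pairing of stimulus times
    and outcomes; p per frequency is the proportion of surrogate powers
    >= the observed power, then BH-FDR corrected across frequencies.

    Returns a frame with columns ``freq, power, p, significant``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p-values")
    rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs, dtype=float)

    binned = bin_performance(trials, window, binwidth, step, min_per_bin)
    n_bins = len(binned)
    # zero-pad so the evaluation grid step (0.5 Hz by default) is exact
    grid_step = np.diff(freqs).min() if freqs.size > 1 else 0.5
    n_pad = max(n_bins, int(round(1.0 / (step * grid_step))))

    t = trials["t_stim"].to_numpy(dtype=float)
    y = trials["outcome"].to_numpy(dtype=float)
    lefts = binned["t"].to_numpy() - binwidth / 2
    member = (t[None, :] >= lefts[:, None] - 1e-12) & (
        t[None, :] < lefts[:, None] + binwidth - 1e-12)
    counts = member.sum(axis=1)
    good = counts >= min_per_bin
    if not good.any():
        raise ValueError("all bins are thinner than min_per_bin")

    centers = binned["t"].to_numpy()

    def interpolate(series_good: np.ndarray) -> np.ndarray:
        """Fill thin/empty bins by linear interpolation over bin centers."""
        if good.all():
            return series_good
        full = np.empty((n_bins,) + series_good.shape[1:])
        for col in range(series_good.shape[1]) if series_good.ndim == 2 else [None]:
            s = series_good if col is None else series_good[:, col]
            f = np.interp(centers, centers[good], s)
            if col is None:
                full[:] = f
            else:
                full[:, col] = f
        return full

    M = member[good].astype(float)
    cnt = counts[good].astype(float)
    obs_series = interpolate(100.0 * (M @ y) / cnt)
    observed = _taper_and_power(obs_series, step, freqs, n_pad)

    count_ge = np.zeros(freqs.size)
    block = 200  # permutations per vectorised block
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.stack([rng.permutation(y) for _ in range(b)], axis=1)
        series = interpolate(100.0 * (M @ perms) / cnt[:, None])
        power = _taper_and_power(series, step, freqs, n_pad)
        count_ge += (power >= observed[:, None]).sum(axis=1)
        done += b
    p = count_ge / n_perm
    sig = inference.fdr_bh(p, q=q)
    return pd.DataFrame({
        "freq": freqs, "power": observed, "p": p, "significant": sig})
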