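"""Movement-locked phase alignment: mean resultant vectors and split-half
spatial correlation.

The mean resultant vector (MRV) of a channel at a time point is the
trial-average of the complex analytic signal; its amplitude-normalized
variant (each trial's value divided by its modulus) is the familiar
inter-trial coherence.  Averaging subjects' normalized MRVs gives an
inter-individual consistency map whose magnitude is high only when subjects
share the movement-locked angle.

The statistical test of phase locking avoids both the dependence on
individual topographies/preferred angles and the channel x time multiple-
comparisons burden: per subject, trials are split at random into two equal
halves, MRVs are computed per half, and the two MRV vectors are correlated
*across channels* with a complex (conjugate) inner-product correlation
r(t).  Under no locking E[Re r(t)] = 0; with locking the halves share
phases and Re r(t) > 0.  Re r(t) is averaged over many random partitions
and submitted to a one-sample group t-test with BH-FDR across time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from . import inference
from .spectral import AnalyticEpochs


@dataclass
class MRVMap:
    """Per-channel, per-time mean resultant vector of one subject."""

    values: np.ndarray        # complex (n_channels, n_times)
    time: np.ndarray
    normalized: bool
    n_trials: int
    channel_labels: list[str]


@dataclass
class SplitHalfResult:
    """Split-half spatial-correlation time course for one subject."""

    time: np.ndarray
    mean_real: np.ndarray     # mean over partitions of Re r(t)
    mean_complex: np.ndarray  # mean over partitions of r(t) (diagnostic)
    n_partitions: int
    n_trials_per_half: int


def mrv(analytic: AnalyticEpochs, normalized: bool = False) -> MRVMap:
    """Trial-mean of the analytic signal per channel and time.

    With ``normalized=True`` each trial's value is first divided by its
    modulus (inter-trial coherence); zero-amplitude samples are excluded
    from the normalized mean with a warning, and cells where every trial
    has zero amplitude are returned as nan.
    """
    vals = analytic.values
    if vals.shape[2] < 2:
        raise ValueError("MRV needs at least 2 trials")
    if normalized:
        amp = np.abs(vals)
        zero = amp == 0
        if zero.any():
            warnings.warn(
                f"{zero.sum()} zero-amplitude sample(s) excluded from the "
                "normalized MRV"
            )
        unit = np.where(zero, 0.0, vals / np.where(zero, 1.0, amp))
        denom = (~zero).sum(axis=2)
        with np.errstate(invalid="ignore"):
            m = unit.sum(axis=2) / denom
        m[denom == 0] = np.nan
    else:
        m = vals.mean(axis=2)
    return MRVMap(values=m, time=analytic.time, normalized=normalized,
                  n_trials=vals.shape[2],
                  channel_labels=list(analytic.channel_labels))


def interindividual_consistency(maps: list[MRVMap]) -> MRVMap:
    """Across-subject average of normalized MRV maps.

    The magnitude of the average is high only where subjects share the
    movement-locked phase angle; its angle is the group-mean locked phase.
    """
    if not maps:
        raise ValueError("need at least one subject map")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape or not np.allclose(m.time, ref.time):
            raise ValueError("subject MRV maps must share the channel/time grid")
        if not m.normalized:
            raise ValueError("inter-individual consistency requires normalized MRVs")
    if not ref.normalized:
        raise ValueError("inter-individual consistency requires normalized MRVs")
    avg = np.mean([m.values for m in maps], axis=0)
    return MRVMap(values=avg, time=ref.time, normalized=True,
                  n_trials=sum(m.n_trials for m in maps),
                  channel_labels=ref.channel_labels)


def spatial_corr(mrv1: np.ndarray, mrv2: np.ndarray) -> np.ndarray:
    """Complex correlation across channels of two MRV vectors per time.

    r(t) = <MRV1(t), conj MRV2(t)> / (||MRV1(t)|| * ||MRV2(t)||), with the
    inner product over the channel axis (axis 0).  |r| <= 1 by
    Cauchy–Schwarz.
    """
    num = np.sum(mrv1 * np.conj(mrv2), axis=0)
    den = np.sqrt(np.sum(np.abs(mrv1) ** 2, axis=0)
                  * np.sum(np.abs(mrv2) ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def split_half_spatial_corr(
    analytic: AnalyticEpochs,
    n_partitions: int = 500,
    rng: np.random.Generator | int | None = None,
) -> SplitHalfResult:
    """Partition-averaged split-half spatial correlation for one subject.

    For each of ``n_partitions`` random partitions the trials are split
    into two equal halves (with an odd trial count, one trial is dropped
    uniformly at random per partition); MRVs are computed per half and
    correlated across channels (:func:`spatial_corr`); Re r(t) is averaged
    over partitions.
    """
    vals = analytic.values  # (ch, time, trials)
    n_ch, n_time, n = vals.shape
    if n < 4:
        raise ValueError("split-half needs at least 4 trials")
    if n_ch < 2:
        raise ValueError("spatial correlation needs at least 2 channels")
    rng = np.random.default_rng(rng)
    half = n // 2

    # indicator matrices (trials x partitions) for the two halves
    ind1 = np.zeros((n, n_partitions))
    ind2 = np.zeros((n, n_partitions))
    for pi in range(n_partitions):
        perm = rng.permutation(n)
        ind1[perm[:half], pi] = 1.0
        ind2[perm[half:2 * half], pi] = 1.0

    flat = vals.reshape(n_ch * n_time, n)
    m1 = (flat @ ind1).reshape(n_ch, n_time, n_partitions) / half
    m2 = (flat @ ind2).reshape(n_ch, n_time, n_partitions) / half
    r = spatial_corr(m1, m2)  # (n_time, n_partitions)
    return SplitHalfResult(
        time=analytic.time,
        mean_real=r.real.mean(axis=1),
        mean_complex=r.mean(axis=1),
        n_partitions=n_partitions,
        n_trials_per_half=half,
    )


def group_phase_locking_test(
    mean_real_r: np.ndarray,
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group test of phase locking from per-subject split-half time courses.

    Parameters
    ----------
    mean_real_r
        Array (n_subjects, n_times) of partition-averaged Re r(t).

    Returns
    -------
    t, p, significant
        Per-time one-sample t statistic of Re r(t) against 0, its p-value,
        and the BH-FDR rejection mask across time.  Time points with zero
        between-subject variance are degenerate: flagged with nan p and
        excluded from the FDR family (with a warning).
    """
    x = np.asarray(mean_real_r, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need (n_subjects >= 3, n_times) input")
    var = x.var(axis=0)
    degenerate = var == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sstats.ttest_1samp(x, 0.0, axis=0)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} time point(s) have zero between-subject "
            "variance; flagged degenerate"
        )
        p = np.where(degenerate, np.nan, p)
    sig = np.zeros(x.shape[1], dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        sig[ok] = inference.fdr_bh(p[ok], q=q)
    return t, p, sig
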