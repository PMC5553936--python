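"""Data containers, file round-trip, trial filtering and force-onset detection.

Conventions used throughout the package:

* times are in seconds, movement onset is 0, negative times precede it;
* trial tables are pandas DataFrames with the fixed column set
  ``subject_id, trial_id, condition, t_move, t_stim, outcome`` where ``t_move``
  is the produced movement time measured from cue offset and ``t_stim`` is the
  stimulus time relative to movement onset (signed);
* epochs are stored channels x samples x trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["subject_id", "trial_id", "condition", "t_move", "t_stim", "outcome"]

#: half-width of the stimulus-time analysis window (s); trials with
#: |t_stim| beyond it are discarded before phase->outcome modelling
ANALYSIS_WINDOW = 0.6


class OnsetNotDetectedError(RuntimeError):
    """Raised when a force trace contains no qualifying movement-onset run."""


class ContainerFormatError(RuntimeError):
    """Raised when an epoch container on disk is malformed."""


@dataclass
class ForceTrace:
    """A single-axis joystick force (voltage) series sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("force trace must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force trace contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class EpochSet:
    """Multichannel epochs aligned to movement or stimulus onset.

    Parameters
    ----------
    data
        Real array of shape (n_channels, n_samples, n_trials).
    fs
        Sampling rate in Hz.
    time
        Time axis in seconds relative to the alignment event, uniformly
        spaced at 1/fs.
    channel_labels
        One label per channel.
    channel_pos
        Optional (n_channels, 2) electrode positions.
    alignment
        Either ``"movement"`` or ``"stimulus"``.
    """

    data: np.ndarray
    fs: float
    time: np.ndarray
    channel_labels: list[str]
    alignment: str = "movement"
    channel_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        n_ch, n_samp, _ = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length does not match data")
        if self.time.shape != (n_samp,):
            raise ValueError("time axis does not match the sample dimension")
        step = np.diff(self.time)
        if n_samp > 1 and not np.allclose(step, 1.0 / self.fs, atol=1e-9):
            raise ValueError("time axis must be uniform with step 1/fs")
        if self.alignment not in ("movement", "stimulus"):
            raise ValueError("alignment must be 'movement' or 'stimulus'")
        if self.channel_pos is not None:
            self.channel_pos = np.asarray(self.channel_pos, dtype=float)
            if self.channel_pos.shape != (n_ch, 2):
                raise ValueError("channel_pos must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the table unchanged."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if not set(np.unique(trials["outcome"])) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if (trials["t_move"] <= 0).any():
        raise ValueError("t_move must be positive (seconds from cue offset)")
    bad = ~trials["condition"].isin(["short", "long"])
    if bad.any():
        raise ValueError("condition must be 'short' or 'long'")
    dup = trials.duplicated(subset=["subject_id", "trial_id"])
    if dup.any():
        raise ValueError("trial_id must be unique within subject")
    return trials


def detect_movement_onset(trace: ForceTrace, run_length: int = 15) -> int:
    """Find movement onset as the start of the first sustained force increase.

    The onset is the first sample of the first run of at least ``run_length``
    consecutive samples whose first difference is strictly positive.  A zero
    or negative difference breaks the run.

    Returns the sample index; onset time in seconds is ``index / trace.fs``.

    Raises
    ------
    OnsetNotDetectedError
        If no qualifying run exists.
    """
    x = trace.samples
    if x.size < run_length + 1:
        raise ValueError(
            f"trace too short: need at least {run_length + 1} samples"
        )
    pos = np.diff(x) > 0
    # run-length encode the boolean difference sign
    idx = 0
    n = pos.size
    while idx < n:
        if pos[idx]:
            end = idx
            while end < n and pos[end]:
                end += 1
            if end - idx >= run_length:
                return idx
            idx = end
        else:
            idx += 1
    raise OnsetNotDetectedError("no onset detected")


def filter_trials(
    trials: pd.DataFrame,
    mode: str,
    phase_time: float | None = None,
) -> pd.DataFrame:
    """Select trials for one of the analysis variants.

    Parameters
    ----------
    trials
        Trial table (see :data:`TRIAL_COLUMNS`).
    mode
        ``"analysis_window"`` keeps trials with |t_stim| <= 0.6 s (inclusive);
        ``"forward_only"`` additionally keeps trials whose stimulus followed
        the phase-estimation time (``t_stim > phase_time``);
        ``"pre_movement"`` keeps trials with the stimulus before movement
        onset (``t_stim < 0``).
    phase_time
        Phase-estimation time in seconds, required for ``forward_only``.
    """
    validate_trials(trials)
    if mode == "analysis_window":
        keep = trials["t_stim"].abs() <= ANALYSIS_WINDOW
    elif mode == "forward_only":
        if phase_time is None:
            raise ValueError("forward_only requires phase_time")
        keep = (trials["t_stim"].abs() <= ANALYSIS_WINDOW) & (
            trials["t_stim"] > phase_time
        )
    elif mode == "pre_movement":
        keep = trials["t_stim"] < 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = trials.loc[keep].copy()
    if out.empty:
        warnings.warn(f"filter_trials({mode!r}) returned an empty table")
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 TSV with the fixed header."""
    validate_trials(trials)
    trials.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    """Read a TSV trial table and validate it."""
    trials = pd.read_csv(path, sep="\t")
    return validate_trials(trials)


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to an HDF5 container.

    Layout: datasets ``/data`` (channels x samples x trials), ``/time``,
    ``/channel_labels`` and optionally ``/channel_pos``; root attributes
    ``fs`` and ``alignment``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset(
            "channel_labels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        if epochs.channel_pos is not None:
            f.create_dataset("channel_pos", data=epochs.channel_pos)
        f.attrs["fs"] = epochs.fs
        f.attrs["alignment"] = epochs.alignment


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet`; errors name the offending dataset/attribute."""
    with h5py.File(path, "r") as f:
        for name in ("data", "time", "channel_labels"):
            if name not in f:
                raise ContainerFormatError(f"container missing dataset '{name}'")
        for attr in ("fs", "alignment"):
            if attr not in f.attrs:
                raise ContainerFormatError(f"container missing attribute '{attr}'")
        data = f["data"][()]
        time = f["time"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]]
        pos = f["channel_pos"][()] if "channel_pos" in f else None
        fs = float(f.attrs["fs"])
        alignment = str(f.attrs["alignment"])
    if data.ndim != 3:
        raise ContainerFormatError("'data' must be channels x samples x trials")
    try:
        return EpochSet(data=data, fs=fs, time=time, channel_labels=labels,
                        alignment=alignment, channel_pos=pos)
    except ValueError as e:
        raise ContainerFormatError(str(e)) from e
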