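"""Raw-EEG preprocessing: band-pass filtering, windowing, standardization.

The pipeline order is fixed: the full trial is filtered first, then cut
into windows (filtering window-by-window would differ at the edges and
is not supported). Standardization operates on derived feature rows,
per subject per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .montage import SEED_62_CHANNELS

__all__ = [
    "EMOTIONS", "Trial", "Window",
    "bandpass_filter", "segment_windows", "zscore_per_session",
]

#: Canonical emotion classes, index = integer label used by the models.
EMOTIONS: tuple[str, ...] = ("negative", "neutral", "positive")


@dataclass
class Trial:
    """One EEG recording of a subject watching a single stimulus."""

    subject_id: str
    session_id: int
    trial_id: int
    samples: np.ndarray          # (62, T) in µV-scale units
    sampling_rate: float         # Hz
    label: str                   # one of EMOTIONS
    channel_names: tuple[str, ...] = SEED_62_CHANNELS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"samples must be (n_channels, time); got {self.samples.shape} for "
                f"{len(self.channel_names)} channels"
            )
        if len(self.channel_names) != 62:
            raise ValueError(f"expected 62 channels, got {len(self.channel_names)}")
        if len(set(self.channel_names)) != 62:
            raise ValueError("channel names must be unique")
        if self.sampling_rate <= 150:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz too low: the 75 Hz band "
                "edge must be below Nyquist"
            )
        if self.label not in EMOTIONS:
            raise ValueError(f"label {self.label!r} not in {EMOTIONS}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Window:
    """A fixed-length segment of a trial; inherits the trial label."""

    samples: np.ndarray          # (62, N)
    sampling_rate: float
    subject_id: str
    session_id: int
    trial_id: int
    window_index: int
    label: str
    channel_names: tuple[str, ...] = SEED_62_CHANNELS


def bandpass_filter(trial: Trial, low: float = 1.0, high: float = 75.0,
                    order: int = 4) -> Trial:
    """Zero-phase Butterworth band-pass of the whole trial.

    A 4th-order design applied forward-backward (``sosfiltfilt``), so the
    effective attenuation is twice the single-pass order and band-interior
    components suffer no group delay.
    """
    nyquist = trial.sampling_rate / 2.0
    if high >= nyquist:
        raise ValueError(
            f"upper edge {high} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz (sampling rate {trial.sampling_rate} Hz)"
        )
    if not 0 < low < high:
        raise ValueError(f"invalid band edges ({low}, {high})")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trial.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, trial.samples, axis=-1)
    return replace(trial, samples=filtered)


def segment_windows(trial: Trial, window_seconds: float = 4.0,
                    overlap_seconds: float = 0.0) -> list[Window]:
    """Cut a trial into contiguous fixed-length windows from time zero.

    The trailing remainder shorter than one window is discarded. A trial
    shorter than one window yields an empty list with a warning.
    """
    if not 0 <= overlap_seconds < window_seconds:
        raise ValueError("overlap must be non-negative and shorter than the window")
    n = int(round(window_seconds * trial.sampling_rate))
    step = int(round((window_seconds - overlap_seconds) * trial.sampling_rate))
    if trial.n_samples < n:
        warnings.warn(
            f"trial {trial.subject_id}/{trial.session_id}/{trial.trial_id}: "
            f"{trial.n_samples} samples shorter than one {n}-sample window; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    windows = []
    idx = 0
    for start in range(0, trial.n_samples - n + 1, step):
        windows.append(Window(
            samples=trial.samples[:, start:start + n],
            sampling_rate=trial.sampling_rate,
            subject_id=trial.subject_id,
            session_id=trial.session_id,
            trial_id=trial.trial_id,
            window_index=idx,
            label=trial.label,
            channel_names=trial.channel_names,
        ))
        idx += 1
    return windows


def zscore_per_session(features: np.ndarray, subject_ids, session_ids,
                       ddof: int = 1) -> np.ndarray:
    """Standardize each feature dimension to zero mean / unit SD within
    every (subject, session) group.

    Sample SD (``ddof=1``) by convention; constant dimensions map to
    zeros with a warning. Groups with a single row are rejected because
    their SD is undefined.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (samples x dims)")
    subject_ids = np.asarray(subject_ids)
    session_ids = np.asarray(session_ids)
    if len(subject_ids) != len(X) or len(session_ids) != len(X):
        raise ValueError("grouping vectors must match the number of rows")
    out = np.empty_like(X)
    keys = np.array([f"{s}\x00{ses}" for s, ses in zip(subject_ids, session_ids)])
    warned = False
    for key in np.unique(keys):
        rows = keys == key
        group = X[rows]
        if group.shape[0] < 2:
            raise ValueError(f"group {key.replace(chr(0), '/')} has a single sample; "
                             "standard deviation undefined")
        mu = group.mean(axis=0)
        sd = group.std(axis=0, ddof=ddof)
        z = np.zeros_like(group)
        nonconst = sd > 0
        z[:, nonconst] = (group[:, nonconst] - mu[nonconst]) / sd[nonconst]
        if not nonconst.all() and not warned:
            warnings.warn("constant feature dimension(s) mapped to zeros during "
                          "z-scoring", stacklevel=2)
            warned = True
        out[rows] = z
    return out
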