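"""Differential-entropy features and demographic encoding.

Per 4-s window, channel and canonical frequency band, the band power
sigma^2 is estimated from the DFT periodogram and turned into a
differential-entropy value under a Gaussian signal model:

    DE = 1/2 * ln(pi * e * sigma^2)        (``paper`` convention)

Note the convention: the full Gaussian differential entropy is
1/2*ln(2*pi*e*sigma^2); the default here omits the factor 2 inside the
logarithm, i.e. it sits exactly 1/2*ln(2) below the standard value.
The offset is constant per feature dimension and vanishes after the
per-session z-scoring, but ``convention="standard"`` is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Trial, Window, segment_windows

__all__ = [
    "BandDefinition", "BANDS", "BandPower", "DEFeatures",
    "band_psd", "differential_entropy", "extract_de",
    "encode_demographics", "DemographicStats", "NATIONALITY_CODES",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, exclusive

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low {self.low} >= high {self.high}")


#: Canonical EEG bands; half-open [low, high) so adjacent bands never
#: share a DFT bin.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


@dataclass
class BandPower:
    """Per-channel band power with its spectral bookkeeping."""

    sigma2: np.ndarray     # (n_channels,) mean periodogram power in the band
    n_bins: int            # number of DFT bins in the band
    spectrum: np.ndarray   # (n_channels, n_rfft) one-sided periodogram


@dataclass
class DEFeatures:
    """Stack of differential-entropy features for one trial."""

    values: np.ndarray     # (n_windows, n_channels, n_bands), nats
    subject_id: str
    session_id: int
    trial_id: int
    label: str
    band_names: tuple[str, ...]


def _periodogram(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram normalized so the bin sum equals the
    time-domain mean square (Parseval-consistent).

    Rectangular window (no taper). Returns (freqs, P) with P shaped
    (..., n_rfft).
    """
    n = samples.shape[-1]
    X = np.fft.rfft(samples, axis=-1)
    P = (np.abs(X) ** 2) / (n * n)
    # fold the negative-frequency half onto the positive bins
    if n % 2 == 0:
        P[..., 1:-1] *= 2.0
    else:
        P[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, P


def band_psd(window: Window | np.ndarray, band: BandDefinition,
             sampling_rate: float | None = None) -> BandPower:
    """Mean periodogram power of a window restricted to one band.

    sigma^2 = (1/N_b) * sum of P[k] over bins with low <= f_k < high.
    At 200 Hz / 4 s the bin spacing is 0.25 Hz.
    """
    if isinstance(window, Window):
        samples, fs = window.samples, window.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        samples, fs = np.asarray(window, dtype=float), sampling_rate
    if not 0 <= band.low and band.high <= fs / 2.0 + 1e-9:
        raise ValueError(f"band {band.name} [{band.low}, {band.high}) outside "
                         f"(0, Nyquist={fs / 2.0}]")
    freqs, P = _periodogram(samples, fs)
    mask = (freqs >= band.low) & (freqs < band.high)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise ValueError(f"band {band.name} contains no DFT bins at this "
                         "window length / sampling rate")
    sigma2 = P[..., mask].sum(axis=-1) / n_bins
    return BandPower(sigma2=np.atleast_1d(sigma2), n_bins=n_bins, spectrum=P)


def differential_entropy(sigma2, convention: str = "paper",
                         floor: float | None = None):
    """Gaussian differential entropy of a signal with power ``sigma2``.

    ``paper``: 1/2*ln(pi*e*sigma2); ``standard``: 1/2*ln(2*pi*e*sigma2).
    Non-positive powers are rejected unless an explicit ``floor`` is
    given, in which case powers are clamped from below first.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if floor is not None:
        s2 = np.maximum(s2, floor)
    if np.any(s2 <= 0):
        raise ValueError("sigma2 must be strictly positive (pass floor=... to clamp)")
    if convention == "paper":
        const = math.pi * math.e
    elif convention == "standard":
        const = 2.0 * math.pi * math.e
    else:
        raise ValueError(f"unknown convention {convention!r}")
    out = 0.5 * np.log(const * s2)
    return float(out) if np.isscalar(sigma2) else out


def extract_de(trial: Trial, bands: tuple[BandDefinition, ...] = BANDS,
               window_seconds: float = 4.0, convention: str = "paper",
               floor: float = 1e-30) -> DEFeatures:
    """Windowed differential-entropy tensor for one (filtered) trial.

    Output shape (n_windows, n_channels, n_bands); the flattened 310-d
    feature vector per window is channel-major then band.
    """
    windows = segment_windows(trial, window_seconds=window_seconds)
    n_ch = len(trial.channel_names)
    values = np.empty((len(windows), n_ch, len(bands)))
    for w, window in enumerate(windows):
        freqs, P = _periodogram(window.samples, window.sampling_rate)
        for b, band in enumerate(bands):
            mask = (freqs >= band.low) & (freqs < band.high)
            sigma2 = P[:, mask].sum(axis=-1) / mask.sum()
            values[w, :, b] = differential_entropy(sigma2, convention=convention,
                                                   floor=floor)
    return DEFeatures(values=values, subject_id=trial.subject_id,
                      session_id=trial.session_id, trial_id=trial.trial_id,
                      label=trial.label, band_names=tuple(b.name for b in bands))


# --------------------------------------------------------------------------
# demographics

#: Dummy coding of nationality: two bits, Chinese is the reference level.
NATIONALITY_CODES: dict[str, tuple[int, int]] = {
    "Chinese": (0, 0),
    "French": (1, 0),
    "German": (0, 1),
}

SEX_CODES: dict[str, int] = {"M": 1, "F": 0}

DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("age", "sex", "nationality_1", "nationality_2")


@dataclass
class DemographicStats:
    """Training-cohort means/SDs used to standardize encoded demographics."""

    mean: np.ndarray  # (4,)
    sd: np.ndarray    # (4,)


def _dummy_code(table: pd.DataFrame) -> np.ndarray:
    required = {"age", "sex", "nationality"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"demographics table missing columns {sorted(missing)}")
    unknown = set(table["nationality"]) - set(NATIONALITY_CODES)
    if unknown:
        raise ValueError(f"unknown nationality level(s) {sorted(unknown)}; the model "
                         f"defines {sorted(NATIONALITY_CODES)}")
    bad_sex = set(table["sex"]) - set(SEX_CODES)
    if bad_sex:
        raise ValueError(f"unknown sex level(s) {sorted(bad_sex)}; expected M/F")
    nat = np.array([NATIONALITY_CODES[n] for n in table["nationality"]], dtype=float)
    out = np.column_stack([
        table["age"].to_numpy(dtype=float),
        np.array([SEX_CODES[s] for s in table["sex"]], dtype=float),
        nat,
    ])
    return out


def fit_demographic_stats(table: pd.DataFrame, ddof: int = 1) -> DemographicStats:
    """Compute standardization statistics from a (training) cohort table."""
    raw = _dummy_code(table)
    if raw.shape[0] < 2:
        raise ValueError("need at least two subjects to fit demographic statistics")
    return DemographicStats(mean=raw.mean(axis=0), sd=raw.std(axis=0, ddof=ddof))


def encode_demographics(table: pd.DataFrame,
                        stats: DemographicStats | None = None) -> np.ndarray:
    """Encode (age, sex, nationality) rows as standardized 4-vectors.

    Columns are (age, sex_bit, nat_bit1, nat_bit2) with nationality
    dummy-coded Chinese (0,0) / French (1,0) / German (0,1), then
    z-scored with ``stats`` (fit on the table itself when omitted —
    only appropriate outside cross-validation). Constant columns map to
    zeros with a warning.
    """
    raw = _dummy_code(table)
    if stats is None:
        stats = fit_demographic_stats(table)
    encoded = np.zeros_like(raw)
    nonconst = stats.sd > 0
    encoded[:, nonconst] = (raw[:, nonconst] - stats.mean[nonconst]) / stats.sd[nonconst]
    if not nonconst.all():
        names = [DEMOGRAPHIC_COLUMNS[i] for i in np.flatnonzero(~nonconst)]
        warnings.warn(f"constant demographic column(s) {names} mapped to zeros",
                      stacklevel=2)
    return encoded
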