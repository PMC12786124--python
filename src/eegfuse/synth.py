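"""Synthetic EEG cohorts with controllable emotion and demographic structure.

The generator emulates the structure of multi-site emotion datasets
recorded with 62-channel 10-20 caps: a few dozen subjects of three
nationalities, three recording sessions each, class-balanced trials over
{negative, neutral, positive}, ages 19-29, and site-specific sex ratios.

Each trial is a sum over the five canonical bands of band-limited
Gaussian noise. The expected in-band power of band ``b`` for a trial is

    baseline[b] * emotion[(label, b)] * prod_g demographic[(g, b)]
               * prod_g interaction[(g, label, b)] * subject_factor[b]

where ``g`` runs over the subject's demographic groups (nationality,
sex code, age dichotomy at 23 years) and the subject factor is
log-normal. On top of this expected value, each (trial, band) draws a
mean-one log-normal fluctuation (``trial_sd``) shared across channels —
the trial-to-trial band-power variability real recordings show; without
it, independent channel noise would make any multichannel band effect
almost perfectly decodable. Band-limiting uses the same Butterworth
design as the preprocessing filter; component powers are pre-compensated
for the measured band-to-band leakage (filter skirts plus
rectangular-window sidelobes), so the composite signal's realized 4-s
window power meets the per-band targets to within a few percent.

Note the interaction map: multiplicative *main* demographic effects
shift the per-band differential entropy by a constant per subject and
are exactly removed by the per-session z-scoring downstream, so only
emotion-by-group interactions can make demographic covariates
informative for classification. Cohorts for fusion experiments should
express demographic structure through ``interaction_effects``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .features import BANDS
from .preprocess import EMOTIONS, Trial

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "subject_groups"]

BAND_NAMES = tuple(b.name for b in BANDS)

#: Subject counts per nationality mirroring the three emulated sites.
_DEFAULT_SUBJECTS = {"Chinese": 15, "French": 8, "German": 8}
#: Recordings per subject at each site (3 sessions x {15, 21, 18} clips).
_DEFAULT_TRIALS = {"Chinese": 45, "French": 63, "German": 54}
#: Site-specific probability of a subject being male (7/15, 5/8, 7/8).
_DEFAULT_P_MALE = {"Chinese": 7 / 15, "French": 5 / 8, "German": 7 / 8}
#: Roughly 1/f-decreasing band powers, arbitrary µV²-scale units.
_DEFAULT_BASELINE = {"delta": 40.0, "theta": 20.0, "alpha": 15.0,
                     "beta": 10.0, "gamma": 5.0}
#: Modest consistent emotion effects: high-frequency power up for
#: positive, down for negative stimuli.
_DEFAULT_EMOTION = {
    ("positive", "gamma"): 1.4, ("positive", "beta"): 1.2,
    ("negative", "gamma"): 0.75, ("negative", "beta"): 0.9,
}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; defaults emulate the
    three-site structure described above."""

    n_subjects_per_nationality: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SUBJECTS))
    trials_per_subject: int | dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TRIALS))
    sessions: int = 3
    trial_seconds: float = 60.0
    sampling_rate: float = 200.0
    age_range: tuple[int, int] = (19, 29)
    sex_probability: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_P_MALE))
    band_power_baseline: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE))
    emotion_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EMOTION))
    demographic_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    subject_sd: float = 0.1
    trial_sd: float = 0.2
    channel_gains: np.ndarray | None = None
    filter_order: int = 4
    seed: int = 0

    def trials_for(self, nationality: str) -> int:
        if isinstance(self.trials_per_subject, dict):
            return self.trials_per_subject[nationality]
        return int(self.trials_per_subject)

    def validate(self) -> None:
        window = 4.0
        if self.trial_seconds < window:
            raise ValueError(
                f"trial_seconds {self.trial_seconds} shorter than one {window}-s window")
        if self.sampling_rate <= 150:
            raise ValueError("sampling_rate must exceed 150 Hz")
        if self.sessions < 1:
            raise ValueError("need at least one session")
        for nat in self.n_subjects_per_nationality:
            t = self.trials_for(nat)
            if t % 3:
                raise ValueError(
                    f"trials_per_subject for {nat} is {t}, not divisible by 3 "
                    "(class balance)")
            if t % self.sessions:
                raise ValueError(f"trials_per_subject for {nat} is {t}, not divisible "
                                 f"by {self.sessions} sessions")
            if (t // self.sessions) % 3:
                raise ValueError(f"per-session trial count for {nat} not divisible "
                                 "by 3 (class balance per session)")
        for name, table in (("band_power_baseline", self.band_power_baseline),
                            ("emotion_effects", self.emotion_effects),
                            ("demographic_effects", self.demographic_effects),
                            ("interaction_effects", self.interaction_effects)):
            for key, value in table.items():
                if not value > 0:
                    raise ValueError(f"{name}[{key!r}] = {value}: factors must be "
                                     "strictly positive")
        unknown = set(self.band_power_baseline) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown band(s) in baseline: {sorted(unknown)}")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if self.trial_sd < 0:
            raise ValueError("trial_sd must be non-negative")
        if self.channel_gains is not None and len(self.channel_gains) != 62:
            raise ValueError("channel_gains must have 62 entries")


@dataclass
class Cohort:
    trials: list[Trial]
    demographics: pd.DataFrame  # columns subject_id, age, sex, nationality

    def subjects(self) -> list[str]:
        return list(self.demographics["subject_id"])


def subject_groups(age: float, sex: str, nationality: str) -> tuple[str, str, str]:
    """Demographic group labels of a subject: nationality, sex code, and
    the age dichotomy at 23 years."""
    return (nationality, sex, "age<=23" if age <= 23 else "age>23")


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                band, fs: float, order: int) -> np.ndarray:
    """White Gaussian noise band-limited with the preprocessing filter
    design (zero-phase Butterworth)."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, white, axis=-1)


@lru_cache(maxsize=8)
def _window_leakage_matrix(fs: float, order: int,
                           window_seconds: float = 4.0) -> np.ndarray:
    """M[i, j] = mean in-band-i power of a 4-s window of a band-j
    component whose full-length in-band power is 1.

    Butterworth skirts and the rectangular-window sidelobes of the
    periodogram move a few percent of each component's power into
    neighbouring bands; composite band targets are pre-compensated by
    solving this (diagonally dominant) system. Estimated once from 500
    windows of noise with a fixed internal seed, then cached.
    """
    rng = np.random.default_rng(123_456_789)
    wl = int(round(window_seconds * fs))
    n = 500 * wl
    freqs_long = np.fft.rfftfreq(n, d=1.0 / fs)
    freqs_win = np.fft.rfftfreq(wl, d=1.0 / fs)
    M = np.zeros((len(BANDS), len(BANDS)))
    for j, band in enumerate(BANDS):
        y = _band_noise(rng, 1, n, band, fs, order)[0]
        Y = np.abs(np.fft.rfft(y)) ** 2 / (n * n)
        Y[1:-1] *= 2.0
        mask_j = (freqs_long >= band.low) & (freqs_long < band.high)
        y *= np.sqrt(1.0 / Y[mask_j].sum())
        W = y.reshape(-1, wl)
        P = np.abs(np.fft.rfft(W, axis=-1)) ** 2 / (wl * wl)
        P[..., 1:-1] *= 2.0
        for i, bi in enumerate(BANDS):
            mask_i = (freqs_win >= bi.low) & (freqs_win < bi.high)
            M[i, j] = P[:, mask_i].sum(axis=-1).mean()
    return M


def _compensate_targets(targets: np.ndarray, fs: float, order: int) -> np.ndarray:
    """Component in-band powers whose composite meets ``targets`` at the
    4-s window level (falls back to the raw targets if compensation
    would require a non-positive component)."""
    M = _window_leakage_matrix(fs, order)
    p = np.linalg.solve(M, targets)
    if np.any(p <= 0):
        warnings.warn("band-power targets too contrasted for leakage "
                      "compensation; using uncompensated targets", stacklevel=2)
        return targets
    return p


def _scale_to_band_power(x: np.ndarray, band, fs: float,
                         target: np.ndarray) -> np.ndarray:
    """Rescale each channel so the realized in-band power equals target."""
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    P = (np.abs(X) ** 2) / (n * n)
    if n % 2 == 0:
        P[..., 1:-1] *= 2.0
    else:
        P[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.low) & (freqs < band.high)
    inband = P[:, mask].sum(axis=-1)
    return x * np.sqrt(target / inband)[:, None]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort; byte-deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gains = (np.ones(62) if spec.channel_gains is None
             else np.asarray(spec.channel_gains, dtype=float))

    demo_rows = []
    trials: list[Trial] = []
    n_samples = int(round(spec.trial_seconds * spec.sampling_rate))

    for nationality in sorted(spec.n_subjects_per_nationality):
        n_subj = spec.n_subjects_per_nationality[nationality]
        p_male = spec.sex_probability.get(nationality, 0.5)
        per_session = spec.trials_for(nationality) // spec.sessions
        for s in range(n_subj):
            subject_id = f"{nationality[:3].upper()}{s + 1:02d}"
            age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
            sex = "M" if rng.random() < p_male else "F"
            demo_rows.append({"subject_id": subject_id, "age": age, "sex": sex,
                              "nationality": nationality})
            groups = subject_groups(age, sex, nationality)
            subj_factor = {b: float(np.exp(rng.normal(0.0, spec.subject_sd)))
                           for b in BAND_NAMES}
            for session in range(1, spec.sessions + 1):
                labels = [EMOTIONS[t % 3] for t in range(per_session)]
                for t, label in enumerate(labels):
                    targets = np.empty(len(BANDS))
                    for bi, band in enumerate(BANDS):
                        power = spec.band_power_baseline.get(band.name, 1.0)
                        power *= spec.emotion_effects.get((label, band.name), 1.0)
                        for g in groups:
                            power *= spec.demographic_effects.get((g, band.name), 1.0)
                            power *= spec.interaction_effects.get(
                                (g, label, band.name), 1.0)
                        power *= subj_factor[band.name]
                        if spec.trial_sd > 0:
                            # mean-one log-normal trial fluctuation
                            power *= float(np.exp(rng.normal(
                                -spec.trial_sd**2 / 2.0, spec.trial_sd)))
                        targets[bi] = power
                    component_power = _compensate_targets(
                        targets, spec.sampling_rate, spec.filter_order)
                    samples = np.zeros((62, n_samples))
                    for bi, band in enumerate(BANDS):
                        component = _band_noise(rng, 62, n_samples, band,
                                                spec.sampling_rate, spec.filter_order)
                        samples += _scale_to_band_power(
                            component, band, spec.sampling_rate,
                            component_power[bi] * gains ** 2)
                    trials.append(Trial(
                        subject_id=subject_id, session_id=session, trial_id=t + 1,
                        samples=samples, sampling_rate=spec.sampling_rate,
                        label=label))
    demographics = pd.DataFrame(demo_rows)
    return Cohort(trials=trials, demographics=demographics)
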