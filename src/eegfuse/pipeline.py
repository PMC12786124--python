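"""From raw cohorts to model-ready feature datasets.

Fixed order: band-pass filter each full trial, window it, extract
differential entropy, z-score per subject per session, then group
consecutive windows into fixed-length sequences per trial (remainder
dropped). Standardization uses each subject's own session statistics —
label-free, so it applies identically to train and test subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import extract_de
from .preprocess import EMOTIONS, bandpass_filter, zscore_per_session
from .synth import Cohort

__all__ = ["FeatureDataset", "prepare_features"]


@dataclass
class FeatureDataset:
    """Per-session-standardized DE features in window and sequence views."""

    # sequence view (recurrent / attention models)
    X_seq: np.ndarray            # (n_seq, W, 62, 5)
    y_seq: np.ndarray            # (n_seq,) ints indexing EMOTIONS
    seq_subjects: np.ndarray     # (n_seq,)
    seq_sessions: np.ndarray
    seq_trials: np.ndarray
    # window view (cnn / gnn)
    X_win: np.ndarray            # (n_win, 62, 5)
    y_win: np.ndarray
    win_subjects: np.ndarray
    win_sessions: np.ndarray
    win_trials: np.ndarray
    win_indices: np.ndarray
    demographics: pd.DataFrame
    sequence_length: int

    @property
    def subjects(self) -> np.ndarray:
        return self.demographics["subject_id"].to_numpy()

    def sample_uids(self, view: str = "seq") -> np.ndarray:
        """Stable per-sample identifiers (for leakage auditing)."""
        if view == "seq":
            ids = zip(self.seq_subjects, self.seq_sessions, self.seq_trials,
                      range(len(self.y_seq)))
        else:
            ids = zip(self.win_subjects, self.win_sessions, self.win_trials,
                      self.win_indices)
        return np.array(["/".join(map(str, t)) for t in ids])


def prepare_features(cohort: Cohort, sequence_length: int = 10,
                     window_seconds: float = 4.0, bandpass: bool = True,
                     convention: str = "paper") -> FeatureDataset:
    """Run the full feature pipeline over a cohort."""
    label_index = {name: i for i, name in enumerate(EMOTIONS)}
    values, subj, sess, trial, widx, labels = [], [], [], [], [], []
    for t in cohort.trials:
        filtered = bandpass_filter(t) if bandpass else t
        de = extract_de(filtered, window_seconds=window_seconds,
                        convention=convention)
        n_w = de.values.shape[0]
        values.append(de.values)
        subj.extend([t.subject_id] * n_w)
        sess.extend([t.session_id] * n_w)
        trial.extend([t.trial_id] * n_w)
        widx.extend(range(n_w))
        labels.extend([label_index[t.label]] * n_w)
    X = np.concatenate(values, axis=0)                       # (n_win, 62, 5)
    n_win, n_ch, n_b = X.shape
    subj = np.array(subj)
    sess = np.array(sess, dtype=int)
    trial = np.array(trial, dtype=int)
    widx = np.array(widx, dtype=int)
    y = np.array(labels, dtype=int)

    flat = zscore_per_session(X.reshape(n_win, n_ch * n_b), subj, sess)
    Xz = flat.reshape(n_win, n_ch, n_b)

    # group consecutive windows of each trial into sequences
    seq_X, seq_y, seq_s, seq_ses, seq_t = [], [], [], [], []
    dropped = 0
    df = pd.DataFrame({"subject": subj, "session": sess, "trial": trial,
                       "widx": widx, "row": np.arange(n_win)})
    for (s, ses, tr), grp in df.groupby(["subject", "session", "trial"], sort=True):
        rows = grp.sort_values("widx")["row"].to_numpy()
        n_full = len(rows) // sequence_length
        if n_full == 0:
            dropped += 1
            continue
        for k in range(n_full):
            block = rows[k * sequence_length:(k + 1) * sequence_length]
            seq_X.append(Xz[block])
            seq_y.append(y[block[0]])
            seq_s.append(s)
            seq_ses.append(ses)
            seq_t.append(tr)
    if dropped:
        warnings.warn(f"{dropped} trial(s) shorter than {sequence_length} windows "
                      "were dropped from the sequence view", stacklevel=2)
    if not seq_X:
        raise ValueError("no trial is long enough for the requested sequence length")
    return FeatureDataset(
        X_seq=np.stack(seq_X).astype(np.float32),
        y_seq=np.array(seq_y, dtype=int),
        seq_subjects=np.array(seq_s),
        seq_sessions=np.array(seq_ses, dtype=int),
        seq_trials=np.array(seq_t, dtype=int),
        X_win=Xz.astype(np.float32),
        y_win=y,
        win_subjects=subj,
        win_sessions=sess,
        win_trials=trial,
        win_indices=widx,
        demographics=cohort.demographics.reset_index(drop=True),
        sequence_length=sequence_length,
    )
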