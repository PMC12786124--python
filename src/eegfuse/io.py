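"""Cohort persistence: HDF5 container + demographics CSV, and EDF reading.

Layout of the HDF5 file: one dataset per trial at
``/<subject_id>/s<session>/t<trial>`` shaped (62, T), with ``label`` and
``sampling_rate`` attributes; channel names stored once at the root.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import Trial
from .synth import Cohort

__all__ = ["save_cohort", "load_cohort", "read_trial_edf",
           "save_features", "load_features", "features_to_long_csv",
           "save_traces", "load_traces",
           "save_checkpoint", "load_checkpoint"]

_EEG_FILE = "eeg.h5"
_DEMO_FILE = "demographics.csv"


def save_cohort(cohort: Cohort, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / _EEG_FILE, "w") as f:
        f.attrs["channel_names"] = list(cohort.trials[0].channel_names)
        for t in cohort.trials:
            ds = f.create_dataset(
                f"{t.subject_id}/s{t.session_id}/t{t.trial_id}",
                data=t.samples.astype(np.float32))
            ds.attrs["label"] = t.label
            ds.attrs["sampling_rate"] = t.sampling_rate
    cohort.demographics.to_csv(out / _DEMO_FILE, index=False)
    return out


def load_cohort(in_dir) -> Cohort:
    root = Path(in_dir)
    demographics = pd.read_csv(root / _DEMO_FILE)
    trials: list[Trial] = []
    with h5py.File(root / _EEG_FILE, "r") as f:
        channel_names = tuple(str(c) for c in f.attrs["channel_names"])
        for subject_id in f:
            for session_key in f[subject_id]:
                for trial_key in f[subject_id][session_key]:
                    ds = f[subject_id][session_key][trial_key]
                    trials.append(Trial(
                        subject_id=subject_id,
                        session_id=int(session_key[1:]),
                        trial_id=int(trial_key[1:]),
                        samples=ds[...].astype(float),
                        sampling_rate=float(ds.attrs["sampling_rate"]),
                        label=str(ds.attrs["label"]),
                        channel_names=channel_names))
    trials.sort(key=lambda t: (t.subject_id, t.session_id, t.trial_id))
    return Cohort(trials=trials, demographics=demographics)


def read_trial_edf(path, subject_id: str, session_id: int, trial_id: int,
                   label: str, channel_names=None) -> Trial:
    """Read one EDF recording into a Trial (channels picked/ordered by
    ``channel_names`` when given)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel_names is not None:
        raw.pick(list(channel_names))
        raw.reorder_channels(list(channel_names))
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Trial(subject_id=subject_id, session_id=session_id, trial_id=trial_id,
                 samples=data, sampling_rate=float(raw.info["sfreq"]),
                 label=label,
                 channel_names=tuple(raw.ch_names))


def save_features(dataset, path) -> Path:
    """Write a FeatureDataset to one HDF5 file with provenance columns."""
    path = Path(path)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.attrs["sequence_length"] = dataset.sequence_length
        for view in ("seq", "win"):
            g = f.create_group(view)
            if view == "seq":
                g.create_dataset("X", data=dataset.X_seq)
                g.create_dataset("y", data=dataset.y_seq)
                g.create_dataset("subject",
                                 data=[str(s) for s in dataset.seq_subjects],
                                 dtype=str_dt)
                g.create_dataset("session", data=dataset.seq_sessions)
                g.create_dataset("trial", data=dataset.seq_trials)
            else:
                g.create_dataset("X", data=dataset.X_win)
                g.create_dataset("y", data=dataset.y_win)
                g.create_dataset("subject",
                                 data=[str(s) for s in dataset.win_subjects],
                                 dtype=str_dt)
                g.create_dataset("session", data=dataset.win_sessions)
                g.create_dataset("trial", data=dataset.win_trials)
                g.create_dataset("window", data=dataset.win_indices)
        demo = f.create_group("demographics")
        for col in dataset.demographics.columns:
            values = dataset.demographics[col].to_numpy()
            if values.dtype == object or values.dtype.kind == "U":
                demo.create_dataset(col, data=[str(v) for v in values],
                                    dtype=str_dt)
            else:
                demo.create_dataset(col, data=values)
    return path


def load_features(path):
    from .pipeline import FeatureDataset

    with h5py.File(path, "r") as f:
        demo = pd.DataFrame({
            col: [v.decode() if isinstance(v, bytes) else v
                  for v in f["demographics"][col][...]]
            for col in f["demographics"]})
        return FeatureDataset(
            X_seq=f["seq/X"][...], y_seq=f["seq/y"][...],
            seq_subjects=f["seq/subject"].asstr()[...],
            seq_sessions=f["seq/session"][...],
            seq_trials=f["seq/trial"][...],
            X_win=f["win/X"][...], y_win=f["win/y"][...],
            win_subjects=f["win/subject"].asstr()[...],
            win_sessions=f["win/session"][...],
            win_trials=f["win/trial"][...],
            win_indices=f["win/window"][...],
            demographics=demo[["subject_id", "age", "sex", "nationality"]],
            sequence_length=int(f.attrs["sequence_length"]),
        )


def features_to_long_csv(dataset, path) -> Path:
    """Long-format window-level table: one row per
    (subject, session, trial, window, channel, band)."""
    from .features import BANDS
    from .montage import SEED_62_CHANNELS
    from .preprocess import EMOTIONS

    n, n_ch, n_b = dataset.X_win.shape
    rows = {
        "subject_id": np.repeat(dataset.win_subjects, n_ch * n_b),
        "session": np.repeat(dataset.win_sessions, n_ch * n_b),
        "trial": np.repeat(dataset.win_trials, n_ch * n_b),
        "window": np.repeat(dataset.win_indices, n_ch * n_b),
        "label": np.repeat([EMOTIONS[y] for y in dataset.y_win], n_ch * n_b),
        "channel": np.tile(np.repeat(SEED_62_CHANNELS[:n_ch], n_b), n),
        "band": np.tile([b.name for b in BANDS[:n_b]], n * n_ch),
        "de": dataset.X_win.ravel(),
    }
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def save_traces(traces, path) -> Path:
    """Serialize a collection of fusion traces (one group per fold)."""
    path = Path(path)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        for i, t in enumerate(traces):
            g = f.create_group(f"fold{i:03d}")
            g.create_dataset("omega1", data=t.omega1)
            g.create_dataset("omega2", data=t.omega2)
            g.create_dataset("L", data=t.L)
            g.create_dataset("subject",
                             data=[str(s) for s in t.subject_ids],
                             dtype=str_dt)
            g.create_dataset("true", data=t.true_labels)
            g.create_dataset("predicted", data=t.predicted_labels)
            g.attrs["demo_columns"] = list(t.demo_columns)
    return path


def load_traces(path):
    from .fusion import FusionTrace

    traces = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            traces.append(FusionTrace(
                omega1=g["omega1"][...], omega2=g["omega2"][...],
                L=g["L"][...], subject_ids=g["subject"].asstr()[...],
                true_labels=g["true"][...],
                predicted_labels=g["predicted"][...],
                demo_columns=tuple(str(c) for c in g.attrs["demo_columns"])))
    return traces


def save_checkpoint(estimator, path) -> Path:
    """Single-file checkpoint: estimator parameters + trained weights."""
    import json

    path = Path(path)
    state = estimator.model_.state_dict()
    meta = {"params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in estimator.get_params().items()},
            "classes": estimator.classes_.tolist(),
            "build": estimator._build_info(),
            "type": type(estimator).__name__}
    np.savez(path, __meta__=np.array(json.dumps(meta)),
             **{f"w{k}": v for k, v in state.items()})
    return path if path.suffix == ".npz" else path.with_name(path.name + ".npz")


def load_checkpoint(path):
    """Rebuild a fitted estimator from a checkpoint file."""
    import json

    from . import fusion, models

    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cls = {"EmotionBackboneClassifier": models.EmotionBackboneClassifier,
           "FusedEmotionClassifier": fusion.FusedEmotionClassifier}[meta["type"]]
    params = meta["params"]
    if "channel_names" in params:
        params["channel_names"] = tuple(params["channel_names"])
    est = cls(**params)
    est._rebuild_for_checkpoint(meta["build"])
    est.model_.load_state_dict(
        {k[1:]: data[k] for k in data.files if k.startswith("w")})
    est.classes_ = np.asarray(meta["classes"])
    return est
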