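"""62-channel 10-20 montage: channel names, scalp coordinates, adjacency.

Coordinates come from MNE's standard 10-05 montage (realistic head,
meters). CB1/CB2 — cerebellar leads present on the 62-channel emotion
caps but absent from the 10-05 nomenclature — are mapped to I1/I2, the
nearest labelled inion-lateral positions.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

__all__ = ["SEED_62_CHANNELS", "channel_positions", "build_adjacency"]

# Standard 62-channel extended 10-20 set used by the SEED-family caps,
# front to back.
SEED_62_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

_ALIASES = {"CB1": "I1", "CB2": "I2"}


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    return {name.upper(): np.asarray(xyz, dtype=float) for name, xyz in pos.items()}


def channel_positions(channel_names) -> np.ndarray:
    """3-D scalp positions in meters, one row per channel.

    Raises ``KeyError`` listing any name that cannot be resolved against
    the standard montage (after alias mapping).
    """
    table = _montage_positions()
    out = np.empty((len(channel_names), 3), dtype=float)
    missing = []
    for i, raw in enumerate(channel_names):
        name = _ALIASES.get(raw.upper(), raw.upper())
        if name in table:
            out[i] = table[name]
        else:
            missing.append(raw)
    if missing:
        raise KeyError(f"channels not in the standard 10-20/10-05 montage: {missing}")
    return out


def build_adjacency(channel_names=SEED_62_CHANNELS, threshold_mm: float = 60.0) -> np.ndarray:
    """Proximity graph over electrodes, symmetrically degree-normalized.

    Two electrodes are connected iff their Euclidean scalp distance is at
    most ``threshold_mm``. Self-loops are added before normalization, so
    the result is D^{-1/2} (A + I) D^{-1/2}: symmetric, non-negative,
    spectral norm <= 1. The 60 mm default makes immediate 10-20
    neighbours (e.g. FP1-FP2) adjacent on a realistic adult head while
    keeping the graph sparse.
    """
    pos = channel_positions(channel_names)
    n = len(channel_names)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1) * 1000.0  # mm
    adj = (dist <= threshold_mm).astype(float)
    np.fill_diagonal(adj, 1.0)
    deg = adj.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return adj * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
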