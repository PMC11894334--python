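"""Electrode montage utilities.

Sensor geometry is represented as unit-sphere 3-D coordinates, one row per
electrode.  The default layout is the Biosemi ABC 128-electrode cap (labels
``A1``..``D32``), obtained from MNE's packaged standard montages and
normalised to unit radius.  Smaller caps are produced by even subsampling of
the 128-channel layout so that reduced test montages still cover the scalp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "biosemi_montage",
    "read_montage_tsv",
    "write_montage_tsv",
    "great_circle_distance",
]


def biosemi_montage(n_channels: int = 128) -> tuple[list[str], np.ndarray]:
    """Return ``(labels, positions)`` for a Biosemi-style cap.

    Parameters
    ----------
    n_channels : int
        Number of electrodes, 1..128.  Values below 128 evenly subsample
        the full cap.

    Returns
    -------
    labels : list of str
    positions : (n_channels, 3) float array on the unit sphere
    """
    if not 1 <= n_channels <= 128:
        raise ValueError("n_channels must be in [1, 128]")
    import mne

    m = mne.channels.make_standard_montage("biosemi128")
    pos = m.get_positions()["ch_pos"]
    labels = list(pos)
    xyz = np.array([pos[ch] for ch in labels], dtype=float)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    if n_channels < 128:
        idx = np.unique(np.round(np.linspace(0, 127, n_channels)).astype(int))
        labels = [labels[i] for i in idx]
        xyz = xyz[idx]
    return labels, xyz


def write_montage_tsv(path, labels, positions) -> None:
    """Write a montage as TSV with columns label, x, y, z (unit sphere)."""
    df = pd.DataFrame(positions, columns=["x", "y", "z"])
    df.insert(0, "label", list(labels))
    df.to_csv(path, sep="\t", index=False)


def read_montage_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].astype(str).tolist()
    xyz = df[["x", "y", "z"]].to_numpy(float)
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("montage contains a zero-length position vector")
    return labels, xyz / norms


def great_circle_distance(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit-sphere points."""
    p = np.asarray(positions, float)
    p = p / np.linalg.norm(p, axis=1, keepdims=True)
    cosd = np.clip(p @ p.T, -1.0, 1.0)
    return np.arccos(cosd)
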