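"""Continuous-recording container and I/O.

A :class:`Recording` holds a channels x time data matrix (muV) together
with its sampling rate, channel labels, an observed/corrupted mask and the
rejection metadata accumulated by the pipeline.  I/O covers delimited text
(one column per channel, header row of labels), an ``.npz`` container, an
interval-annotation CSV, and — when ``mne`` is importable — EDF/BDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_recording_csv",
    "write_recording_csv",
    "read_mask_csv",
    "write_mask_csv",
    "load_npz",
    "save_npz",
    "read_annotations_csv",
    "annotations_to_bad_mask",
    "read_edf",
]


@dataclass
class Recording:
    """Channels x time recording with mask and rejection metadata.

    ``mask`` is ``True`` where an entry is observed (usable) and ``False``
    where it is corrupted.
    """

    data: np.ndarray
    fs: float
    channels: list[str] = None
    mask: np.ndarray = None
    rejected_channels: list[int] = field(default_factory=list)
    rejected_timepoints: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        c, t = self.data.shape
        if self.channels is None:
            self.channels = [f"E{i + 1}" for i in range(c)]
        if len(self.channels) != c:
            raise ValueError("channel label count mismatch")
        if self.mask is None:
            self.mask = np.ones((c, t), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            self.fs,
            list(self.channels),
            self.mask.copy(),
            list(self.rejected_channels),
            list(self.rejected_timepoints),
        )


def write_recording_csv(rec: Recording, path) -> None:
    """One column per channel, header row of channel labels."""
    pd.DataFrame(rec.data.T, columns=rec.channels).to_csv(path, index=False)


def read_recording_csv(path, fs: float) -> Recording:
    df = pd.read_csv(path)
    return Recording(df.to_numpy().T, fs=fs, channels=list(df.columns))


def write_mask_csv(mask: np.ndarray, path) -> None:
    np.savetxt(path, mask.astype(int), fmt="%d", delimiter=",")


def read_mask_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=int).astype(bool)


def save_npz(rec: Recording, path) -> None:
    np.savez_compressed(
        path,
        data=rec.data,
        fs=rec.fs,
        channels=np.asarray(rec.channels),
        mask=rec.mask,
        rejected_channels=np.asarray(rec.rejected_channels, dtype=int),
        rejected_timepoints=np.asarray(rec.rejected_timepoints, dtype=int),
    )


def load_npz(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            z["data"],
            float(z["fs"]),
            [str(c) for c in z["channels"]],
            z["mask"],
            z["rejected_channels"].tolist(),
            z["rejected_timepoints"].tolist(),
        )


def read_annotations_csv(path) -> pd.DataFrame:
    """Interval annotations: columns channel_label, start_sample, end_sample
    (0-based, half-open)."""
    df = pd.read_csv(path)
    required = {"channel_label", "start_sample", "end_sample"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    return df


def annotations_to_bad_mask(ann: pd.DataFrame, rec: Recording) -> np.ndarray:
    """Expand interval annotations into a bad-entry boolean matrix.

    The wildcard label ``*`` marks the interval on every channel.
    """
    bad = np.zeros(rec.data.shape, dtype=bool)
    index = {lab: i for i, lab in enumerate(rec.channels)}
    for _, row in ann.iterrows():
        lo = max(0, int(row.start_sample))
        hi = min(rec.n_samples, int(row.end_sample))
        lab = str(row.channel_label)
        if lab == "*":
            bad[:, lo:hi] = True
        else:
            bad[index[lab], lo:hi] = True
    return bad


def read_edf(path) -> Recording:
    """Read a continuous EDF/BDF recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF/BDF requires the 'mne' package") from exc
    path = str(Path(path))
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names))
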