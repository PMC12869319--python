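"""In-memory containers for epoched EEG and subject-level ERPs.

Conventions
-----------
* Potentials are in microvolts (µV).
* Arrays are ``(epochs|subjects, electrodes, timeframes)``; a "timeframe"
  (TF) is one sample at ``sampling_rate``.
* ``onset_index`` is the first post-stimulus sample; samples before it are
  the baseline period.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "ErpSet", "QualityReport", "default_electrode_labels"]


def default_electrode_labels(n_electrodes: int) -> list[str]:
    """Biosemi-style alphabetic labels (A1..A32, B1..B32, ...)."""
    labels = []
    for i in range(n_electrodes):
        bank, pos = divmod(i, 32)
        labels.append(f"{chr(ord('A') + bank)}{pos + 1}")
    return labels


@dataclass
class EpochSet:
    """Single-subject epoched EEG around stimulus onset.

    Parameters
    ----------
    data
        ``(n_epochs, n_electrodes, n_timeframes)`` array of potentials, µV.
    sampling_rate
        Sampling rate in Hz.
    onset_index
        Index of the first post-onset timeframe (number of baseline samples).
    metadata
        One row per epoch. Recognised columns (all optional):
        ``trial_type`` ('Go'/'NoGo'), ``correct`` (bool), ``item_id``,
        ``liking`` (0-100 VAS), ``trained_nogo`` (bool), ``session``.
    electrodes
        Electrode labels; defaults to a Biosemi-style montage naming.
    """

    data: np.ndarray
    sampling_rate: float
    onset_index: int
    metadata: pd.DataFrame | None = None
    electrodes: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, electrodes, timeframes)")
        if not 0 <= self.onset_index <= self.data.shape[2]:
            raise ValueError("onset_index outside the epoch")
        if self.electrodes is None:
            self.electrodes = default_electrode_labels(self.data.shape[1])
        if self.metadata is not None and len(self.metadata) != len(self):
            raise ValueError("metadata length must match the number of epochs")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timeframes(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-timeframe latency relative to onset, in ms."""
        idx = np.arange(self.n_timeframes) - self.onset_index
        return idx * 1000.0 / self.sampling_rate

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        meta = None
        if self.metadata is not None:
            meta = self.metadata.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            meta = meta.reset_index(drop=True)
        return EpochSet(self.data[mask], self.sampling_rate, self.onset_index,
                        meta, list(self.electrodes))

    # -- interop ---------------------------------------------------------
    def to_mne(self):
        """Convert to an :class:`mne.EpochsArray` (volts, standard montage-free info)."""
        import mne

        info = mne.create_info(self.electrodes, self.sampling_rate, ch_types="eeg")
        tmin = -self.onset_index / self.sampling_rate
        return mne.EpochsArray(self.data * 1e-6, info, tmin=tmin, verbose="error")

    @classmethod
    def from_mne(cls, epochs, metadata: pd.DataFrame | None = None) -> "EpochSet":
        """Build from an mne Epochs object (converted volts → µV)."""
        data = epochs.get_data(copy=True) * 1e6
        sfreq = float(epochs.info["sfreq"])
        onset = int(round(-epochs.tmin * sfreq))
        meta = metadata if metadata is not None else epochs.metadata
        return cls(data, sfreq, onset, meta, list(epochs.ch_names))


@dataclass
class ErpSet:
    """Per-subject averaged ERPs for one condition/session.

    ``data`` is ``(n_subjects, n_electrodes, n_timeframes)`` in µV; maps are
    expected (but not forced) to be average-referenced.
    """

    data: np.ndarray
    sampling_rate: float
    onset_index: int
    subjects: list | None = None
    electrodes: list[str] | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, electrodes, timeframes)")
        if self.subjects is None:
            self.subjects = list(range(self.data.shape[0]))
        if self.electrodes is None:
            self.electrodes = default_electrode_labels(self.data.shape[1])

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timeframes(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        idx = np.arange(self.n_timeframes) - self.onset_index
        return idx * 1000.0 / self.sampling_rate

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["onset_index"] = self.onset_index
            if self.session is not None:
                f.attrs["session"] = self.session
            f.create_dataset("subjects", data=np.array([str(s) for s in self.subjects], dtype="S"))
            f.create_dataset("electrodes", data=np.array(self.electrodes, dtype="S"))

    @classmethod
    def load_h5(cls, path) -> "ErpSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][...],
                sampling_rate=float(f.attrs["sampling_rate"]),
                onset_index=int(f.attrs["onset_index"]),
                subjects=[s.decode() for s in f["subjects"][...]],
                electrodes=[s.decode() for s in f["electrodes"][...]],
                session=f.attrs.get("session"),
            )


@dataclass
class QualityReport:
    """Data-quality summary of one subject's epoch-to-ERP reduction."""

    n_epochs_in: int
    n_epochs_kept: int
    pct_epochs_jump_rejected: float
    pct_epochs_amplitude_rejected: float
    n_interpolated_electrodes: int = 0

    def __post_init__(self) -> None:
        for pct in (self.pct_epochs_jump_rejected, self.pct_epochs_amplitude_rejected):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))
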