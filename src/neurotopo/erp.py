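"""Epoch-level ERP pipeline: selection, baseline correction, artifact
rejection, averaging, common-average referencing, and global field power.

The pipeline ingests already-cleaned epoched data (band-pass filtering,
line-noise removal, blink correction and bad-channel interpolation are
upstream concerns; the number of interpolated electrodes is carried as
metadata only). Applied to a subject's epochs, the stage order is:

    select → baseline-correct → reject jumps (>30 µV/TF)
           → reject amplitudes (>80 µV) → average → common-average reference

Both rejection rules use a strict inequality: an epoch with a step of
exactly 30 µV, or a peak of exactly ±80 µV, is kept.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet, QualityReport

__all__ = [
    "average_erp",
    "baseline_correct",
    "common_average_reference",
    "gfp",
    "gfp_series",
    "preprocess_epochs",
    "reject_amplitude",
    "reject_jump",
    "select_epochs",
]

JUMP_THRESHOLD_UV = 30.0
AMPLITUDE_THRESHOLD_UV = 80.0


def gfp(scalp_map) -> float:
    """Global field power of one scalp map (µV).

    GFP = sqrt( (1/N_e) * sum_i (v_i - v̄)^2 ), the root-mean-square
    deviation of the electrode potentials from their across-electrode mean.
    It is reference-independent: adding a constant to every electrode leaves
    it unchanged.
    """
    v = np.asarray(scalp_map, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("a scalp map needs at least 2 electrodes")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def gfp_series(maps: np.ndarray, electrode_axis: int = -2) -> np.ndarray:
    """GFP along time for an (..., electrodes, timeframes) array."""
    maps = np.asarray(maps, dtype=float)
    if maps.shape[electrode_axis] < 2:
        raise ValueError("a scalp map needs at least 2 electrodes")
    centered = maps - maps.mean(axis=electrode_axis, keepdims=True)
    return np.sqrt(np.mean(centered ** 2, axis=electrode_axis))


def select_epochs(epochs: EpochSet, correct_rejection: bool = False,
                  min_liking: float | None = None,
                  trained_nogo_only: bool = False) -> EpochSet:
    """Keep epochs satisfying all active criteria (order preserved).

    ``correct_rejection`` keeps successful NoGo trials only; ``min_liking``
    keeps items rated at or above the threshold (a rating of exactly 60
    passes the appetitive-item rule "60 or above"); ``trained_nogo_only``
    restricts to items categorized as NoGo during training.
    """
    if not (correct_rejection or min_liking is not None or trained_nogo_only):
        return epochs
    meta = epochs.metadata
    if meta is None:
        raise ValueError("selection criteria require epoch metadata")
    mask = np.ones(len(epochs), dtype=bool)
    if correct_rejection:
        for col in ("trial_type", "correct"):
            if col not in meta:
                raise ValueError(f"criterion needs metadata column {col!r}")
        mask &= (meta["trial_type"].to_numpy() == "NoGo") & meta["correct"].to_numpy().astype(bool)
    if min_liking is not None:
        if "liking" not in meta:
            raise ValueError("criterion needs metadata column 'liking'")
        mask &= meta["liking"].to_numpy() >= min_liking
    if trained_nogo_only:
        if "trained_nogo" not in meta:
            raise ValueError("criterion needs metadata column 'trained_nogo'")
        mask &= meta["trained_nogo"].to_numpy().astype(bool)
    return epochs.subset(mask)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch/electrode's pre-onset mean from the whole epoch."""
    if epochs.onset_index == 0:
        raise ValueError("no pre-onset samples to form a baseline")
    base = epochs.data[:, :, :epochs.onset_index].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.sampling_rate, epochs.onset_index,
                    epochs.metadata, list(epochs.electrodes))


def reject_jump(epochs: EpochSet,
                threshold: float = JUMP_THRESHOLD_UV) -> tuple[EpochSet, np.ndarray]:
    """Reject epochs with a sample-to-sample step greater than ``threshold`` µV.

    Returns the surviving epochs and the indices of the rejected ones.
    """
    if epochs.n_timeframes < 2:
        raise ValueError("jump detection needs at least 2 timeframes")
    steps = np.abs(np.diff(epochs.data, axis=2))
    bad = steps.max(axis=(1, 2)) > threshold
    return epochs.subset(~bad), np.flatnonzero(bad)


def reject_amplitude(epochs: EpochSet,
                     threshold: float = AMPLITUDE_THRESHOLD_UV) -> tuple[EpochSet, np.ndarray]:
    """Reject epochs with any |potential| greater than ``threshold`` µV.

    The bound is symmetric: a −81 µV trough is rejected like a +81 µV peak.
    """
    bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    return epochs.subset(~bad), np.flatnonzero(bad)


def common_average_reference(maps: np.ndarray, electrode_axis: int = -2) -> np.ndarray:
    """Re-express maps relative to the across-electrode mean (sums to zero)."""
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=electrode_axis, keepdims=True)


def average_erp(epochs: EpochSet, n_epochs_in: int | None = None,
                n_jump_rejected: int = 0, n_amplitude_rejected: int = 0,
                n_interpolated_electrodes: int = 0) -> tuple[np.ndarray, QualityReport]:
    """Average surviving epochs into the subject ERP and re-reference it.

    Returns the ``(electrodes, timeframes)`` common-average-referenced ERP
    and a :class:`QualityReport`. Rejection counts, if the caller tracked
    them, feed the report's percentages.
    """
    n_kept = len(epochs)
    if n_kept == 0:
        raise ValueError("no surviving epochs: subject must be excluded")
    if n_epochs_in is None:
        n_epochs_in = n_kept + n_jump_rejected + n_amplitude_rejected
    erp = common_average_reference(epochs.data.mean(axis=0))
    report = QualityReport(
        n_epochs_in=n_epochs_in,
        n_epochs_kept=n_kept,
        pct_epochs_jump_rejected=100.0 * n_jump_rejected / n_epochs_in,
        pct_epochs_amplitude_rejected=100.0 * n_amplitude_rejected / n_epochs_in,
        n_interpolated_electrodes=n_interpolated_electrodes,
    )
    return erp, report


def preprocess_epochs(epochs: EpochSet, correct_rejection: bool = False,
                      min_liking: float | None = None,
                      trained_nogo_only: bool = False,
                      jump_threshold: float = JUMP_THRESHOLD_UV,
                      amplitude_threshold: float = AMPLITUDE_THRESHOLD_UV,
                      n_interpolated_electrodes: int = 0) -> tuple[np.ndarray, QualityReport]:
    """Run the full epoch-to-ERP stage chain for one subject."""
    selected = select_epochs(epochs, correct_rejection=correct_rejection,
                             min_liking=min_liking, trained_nogo_only=trained_nogo_only)
    corrected = baseline_correct(selected)
    kept, jump_idx = reject_jump(corrected, jump_threshold)
    kept, amp_idx = reject_amplitude(kept, amplitude_threshold)
    return average_erp(kept, n_epochs_in=len(selected),
                       n_jump_rejected=len(jump_idx),
                       n_amplitude_rejected=len(amp_idx),
                       n_interpolated_electrodes=n_interpolated_electrodes)
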