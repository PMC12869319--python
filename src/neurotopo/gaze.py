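"""Gaze-index computation and sign-tracking-bias estimation.

During Pavlovian conditioning, a fractal cue (CS) appears on one side of
the screen and its monetary value (US) later appears on the other. The
gaze index of a trial is ``p(CS) − p(US)``: the difference in fixation-time
proportions on the cue versus the outcome location during the analysis
window (the third second of cue presentation). An index of +1 means
exclusive fixation on the cue, −1 exclusive fixation on the outcome
location.

The sign-tracking bias β1 of a subject is the least-squares slope of the
gaze index on the cue's reward value (CHF). Following the defining formula
``p(CS) − p(US) = β1 × value + ε`` the regression runs through the origin
by default; an intercept can be requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AoiLayout",
    "ForcedChoiceResult",
    "GazeTrial",
    "SignTrackingBias",
    "fixation_proportions",
    "forced_choice_error_rate",
    "gaze_index",
    "mad_outlier_mask",
    "sign_tracking_bias",
]

#: Analysis window relative to CS onset: the third second of presentation.
DEFAULT_WINDOW_S = (2.0, 3.0)

#: Forced-choice learning check: exclude above this error rate (strictly).
FORCED_CHOICE_MAX_ERROR = 0.10

#: Trials with less than this fraction of valid samples are flagged invalid.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class GazeTrial:
    """Fixation proportions of one conditioning trial."""

    trial_index: int
    cs_value: float
    p_cs: float
    p_us: float
    p_bg: float
    valid_fraction: float = 1.0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.p_cs + self.p_us + self.p_bg > 1.0 + 1e-9:
            raise ValueError("fixation proportions exceed 1")


@dataclass(frozen=True)
class SignTrackingBias:
    """Per-subject sign-tracking bias with fit diagnostics."""

    beta1: float
    stderr: float
    n_trials_used: int
    residual_sd: float
    intercept: float | None = None
    subject_id: object = None


@dataclass(frozen=True)
class ForcedChoiceResult:
    error_rate: float
    n_trials: int
    excluded: bool


@dataclass(frozen=True)
class AoiLayout:
    """Rectangular areas of interest for the two stimulus positions.

    Rectangles are ``(x0, y0, x1, y1)`` in pixels, bounds inclusive;
    everything outside both rectangles is background.
    """

    left: tuple[float, float, float, float]
    right: tuple[float, float, float, float]

    def _inside(self, rect, x, y):
        x0, y0, x1, y1 = rect
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    def classify(self, x: np.ndarray, y: np.ndarray, cs_side: str) -> np.ndarray:
        """Label each sample 'cs', 'us' or 'bg' given the cue's side."""
        cs_rect = self.left if cs_side == "left" else self.right
        us_rect = self.right if cs_side == "left" else self.left
        out = np.full(len(x), "bg", dtype=object)
        out[self._inside(us_rect, x, y)] = "us"
        out[self._inside(cs_rect, x, y)] = "cs"
        return out


def fixation_proportions(samples: pd.DataFrame, aoi: AoiLayout, cs_side: str,
                         cs_value: float, trial_index: int = 0,
                         window_s: tuple[float, float] = DEFAULT_WINDOW_S,
                         min_valid_fraction: float = MIN_VALID_FRACTION) -> GazeTrial:
    """Reduce a trial's gaze sample stream to fixation proportions.

    ``samples`` needs columns ``t_s`` (seconds from CS onset), ``x_px``,
    ``y_px`` and boolean ``valid``. Proportions use valid-sample time within
    the half-open window as denominator. A trial whose valid fraction falls
    below ``min_valid_fraction`` (or that has no valid sample at all) is
    flagged invalid and excluded from the bias regression.
    """
    t = samples["t_s"].to_numpy(dtype=float)
    in_win = (t >= window_s[0]) & (t < window_s[1])
    win = samples.loc[in_win]
    n_total = len(win)
    valid = win["valid"].to_numpy(dtype=bool) if n_total else np.array([], bool)
    n_valid = int(valid.sum())
    valid_fraction = n_valid / n_total if n_total else 0.0
    if n_valid == 0 or valid_fraction < min_valid_fraction:
        return GazeTrial(trial_index, cs_value, np.nan, np.nan, np.nan,
                         valid_fraction, valid=False)
    labels = aoi.classify(win["x_px"].to_numpy(float)[valid],
                          win["y_px"].to_numpy(float)[valid], cs_side)
    return GazeTrial(
        trial_index, cs_value,
        p_cs=float(np.mean(labels == "cs")),
        p_us=float(np.mean(labels == "us")),
        p_bg=float(np.mean(labels == "bg")),
        valid_fraction=valid_fraction,
    )


def gaze_index(trial: GazeTrial) -> float:
    """Gaze index of a valid trial: p(CS) − p(US), in [−1, 1]."""
    if not trial.valid:
        raise ValueError("gaze index is undefined for an invalid trial")
    return trial.p_cs - trial.p_us


def _as_index_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    """Extract (cs_value, gaze index) from GazeTrials or a proportions table."""
    if isinstance(trials, pd.DataFrame):
        df = trials
        if "valid_fraction" in df:
            df = df[df["valid_fraction"] >= MIN_VALID_FRACTION]
        return df["cs_value"].to_numpy(float), (df["p_cs"] - df["p_us"]).to_numpy(float)
    kept = [t for t in trials if t.valid]
    return (np.array([t.cs_value for t in kept], float),
            np.array([gaze_index(t) for t in kept], float))


def sign_tracking_bias(trials, include_intercept: bool = False,
                       subject_id=None) -> SignTrackingBias:
    """Least-squares slope of the gaze index on the cue reward value.

    Accepts a sequence of :class:`GazeTrial` or a DataFrame with columns
    ``cs_value, p_cs, p_us`` (and optionally ``valid_fraction``). Invalid
    trials are dropped. The defining formula carries no intercept; pass
    ``include_intercept=True`` to add one.
    """
    x, y = _as_index_arrays(trials)
    n = x.size
    if n < 2 or np.unique(x).size < 2:
        raise ValueError("bias estimation needs >= 2 valid trials with distinct cue values")
    if include_intercept:
        X = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = n - 2
        resid_sd = float(np.sqrt(resid @ resid / dof))
        xc = x - x.mean()
        stderr = resid_sd / float(np.sqrt(xc @ xc))
        return SignTrackingBias(float(coef[0]), stderr, n, resid_sd,
                                intercept=float(coef[1]), subject_id=subject_id)
    sxx = float(x @ x)
    beta1 = float(x @ y) / sxx
    resid = y - beta1 * x
    dof = n - 1
    resid_sd = float(np.sqrt(resid @ resid / dof))
    stderr = resid_sd / np.sqrt(sxx)
    return SignTrackingBias(beta1, stderr, n, resid_sd, subject_id=subject_id)


def forced_choice_error_rate(choices: pd.DataFrame,
                             max_error_rate: float = FORCED_CHOICE_MAX_ERROR) -> ForcedChoiceResult:
    """Error rate of the forced-choice learning check.

    ``choices`` needs ``first_value``, ``second_value`` and ``chosen``
    ('first'/'second'). An error is choosing the lower-valued cue. The
    exclusion rule is strict: exactly 10% errors (3 of 30) is kept, 4 of 30
    is excluded.
    """
    if choices["chosen"].isna().any():
        raise ValueError("missing choices")
    chose_first = choices["chosen"].to_numpy() == "first"
    first_higher = choices["first_value"].to_numpy() > choices["second_value"].to_numpy()
    errors = chose_first != first_higher
    rate = float(errors.mean())
    return ForcedChoiceResult(rate, len(choices), excluded=rate > max_error_rate)


def mad_outlier_mask(values, k: float = 3.0) -> np.ndarray:
    """Keep-mask for values within k·MAD of the median.

    MAD is the raw median absolute deviation (no normal-consistency
    factor). A value is kept iff ``|x − median| <= k·MAD``. When MAD is 0
    (over half the values identical) everything is kept and a warning is
    issued, since the band would otherwise be degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier detection needs at least 3 values")
    med = float(np.median(x))
    mad = float(stats.median_abs_deviation(x, scale=1.0))
    if mad == 0.0:
        warnings.warn("MAD is zero; keeping all values", RuntimeWarning, stacklevel=2)
        return np.ones(x.size, dtype=bool)
    return np.abs(x - med) <= k * mad
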