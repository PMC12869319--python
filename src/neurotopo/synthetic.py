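"""Synthetic data generators with known ground truth.

Every downstream stage (gaze-bias estimation, ERP reduction, topographic
permutation statistics, behavioral correlations) can be exercised without
any recorded data. The generators emulate:

* multi-subject average-referenced ERP sets in which a chosen scalp
  topography covaries with a subject-level variable inside a latency
  window, on top of spatially correlated AR(1) noise,
* per-trial gaze indices following ``index = β1 × cue value + ε``,
* Go/NoGo trial tables with configurable reaction-time distribution and
  commission-error rate, optionally coupled to the subject covariate,
* pre/post visual-analogue liking ratings with a calibrated devaluation
  effect on trained-NoGo items.

All generators are bitwise-reproducible under a fixed seed. Default rates
are anchored to the observed sample of the study design these tasks come
from: ~5% commission errors, ~300 ms mean reaction time, baseline liking
~69 ± 14 VAS points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ErpSet
from .erp import gfp

__all__ = [
    "ErpSimConfig",
    "random_scalp_map",
    "simulate_erp_set",
    "simulate_gaze_subject",
    "simulate_gng_behavior",
    "simulate_liking",
]


def random_scalp_map(n_electrodes: int, rng: np.random.Generator) -> np.ndarray:
    """Random zero-mean (average-referenced) scalp map with unit GFP."""
    v = rng.standard_normal(n_electrodes)
    v -= v.mean()
    return v / gfp(v)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("covariate has zero variance")
    return (x - x.mean()) / sd


@dataclass
class ErpSimConfig:
    """Configuration of the ERP-set generator.

    Parameters
    ----------
    n_subjects, n_electrodes, n_timeframes
        Array dimensions. 64 electrodes matches the montage of the emulated
        recordings; tests typically scale electrodes/timeframes down.
    sampling_rate
        Hz; with ``onset_index`` defines the latency axis.
    effect_window
        Half-open timeframe interval ``[t0, t1)`` where the covariate-coupled
        topography is injected.
    coupling_map
        Zero-mean, unit-GFP topography of the covariate effect. Drawn from
        the seed when omitted.
    coupling_strength
        µV of that topography added per covariate standard deviation;
        0 gives a null dataset.
    noise_sd
        Marginal standard deviation (µV) of the additive noise at each
        electrode/timeframe.
    noise_spatial_rank
        Number of random zero-mean topographies mixed to produce spatially
        correlated noise.
    noise_ar1
        Lag-one autocorrelation of each noise source over timeframes.
    background_components
        Number of smooth (Gaussian time course) components shared by all
        subjects — the grand-average ERP shape.
    """

    n_subjects: int
    n_electrodes: int = 64
    n_timeframes: int = 100
    sampling_rate: float = 1024.0
    onset_index: int = 0
    effect_window: tuple[int, int] = (40, 60)
    coupling_map: np.ndarray | None = None
    coupling_strength: float = 0.0
    noise_sd: float = 1.0
    noise_spatial_rank: int = 8
    noise_ar1: float = 0.5
    background_components: int = 3
    background_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.effect_window
        if not 0 <= t0 < t1 <= self.n_timeframes:
            raise ValueError("effect_window must satisfy 0 <= t0 < t1 <= n_timeframes")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.coupling_map is not None:
            m = np.asarray(self.coupling_map, dtype=float)
            if m.shape != (self.n_electrodes,):
                raise ValueError("coupling_map has wrong length")
            if abs(m.sum()) > 1e-6 * max(1.0, np.abs(m).max()):
                raise ValueError("coupling_map must be zero-mean (average-referenced)")
            self.coupling_map = m


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], a: float) -> np.ndarray:
    """AR(1) series along the last axis with unit marginal variance."""
    innov = rng.standard_normal(shape) * np.sqrt(1.0 - a * a)
    out = np.empty(shape)
    out[..., 0] = rng.standard_normal(shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = a * out[..., t - 1] + innov[..., t]
    return out


def _subject_noise(rng: np.random.Generator, cfg: ErpSimConfig) -> np.ndarray:
    """Spatially correlated AR(1) noise for all subjects, (S, E, T), sd = noise_sd."""
    rank = cfg.noise_spatial_rank
    mixing = np.stack([random_scalp_map(cfg.n_electrodes, rng) for _ in range(rank)], axis=1)
    sources = _ar1_noise(rng, (cfg.n_subjects, rank, cfg.n_timeframes), cfg.noise_ar1)
    noise = np.einsum("er,srt->set", mixing, sources)
    # per-electrode variance of the mixture varies; rescale to the target sd
    scale = cfg.noise_sd / np.sqrt(np.mean(mixing ** 2) * rank)
    return noise * scale


def simulate_erp_set(config: ErpSimConfig, covariate,
                     sessions: int = 1,
                     session_effect_map: np.ndarray | None = None,
                     session_effect_strength: float = 0.0,
                     session_effect_window: tuple[int, int] | None = None):
    """Generate one (or a pre/post pair of) multi-subject ERP set(s).

    ``covariate`` is one value per subject (e.g. the sign-tracking bias);
    it is z-scored internally so ``coupling_strength`` is in µV per
    covariate SD. Subject ``s`` at timeframe ``t`` receives::

        background(t) + 1[t in effect_window] * strength * z_s * coupling_map
                      + 1[post session] * 1[t in session_window] * session_map
                      + noise_s(t)

    Every generated map is average-referenced by construction. Returns
    ``(erps, ground_truth)`` for one session, or ``(pre, post, ground_truth)``
    for two; ``ground_truth`` records the injected maps and windows.
    """
    cfg = config
    beta1 = np.asarray(covariate, dtype=float)
    if beta1.shape != (cfg.n_subjects,):
        raise ValueError("covariate length must equal n_subjects")
    if sessions not in (1, 2):
        raise ValueError("sessions must be 1 or 2")
    rng = np.random.default_rng(cfg.seed)

    coupling_map = cfg.coupling_map
    if coupling_map is None:
        coupling_map = random_scalp_map(cfg.n_electrodes, rng)

    # smooth shared background: zero-mean maps with Gaussian time courses
    t = np.arange(cfg.n_timeframes)
    background = np.zeros((cfg.n_electrodes, cfg.n_timeframes))
    for _ in range(cfg.background_components):
        center = rng.uniform(0, cfg.n_timeframes)
        width = rng.uniform(cfg.n_timeframes / 20, cfg.n_timeframes / 5)
        course = np.exp(-0.5 * ((t - center) / width) ** 2)
        background += cfg.background_scale * np.outer(random_scalp_map(cfg.n_electrodes, rng), course)

    z = _zscore(beta1)
    t0, t1 = cfg.effect_window
    effect = np.zeros((cfg.n_subjects, cfg.n_electrodes, cfg.n_timeframes))
    effect[:, :, t0:t1] = cfg.coupling_strength * z[:, None, None] * coupling_map[None, :, None]

    ground_truth = {
        "coupling_map": coupling_map,
        "coupling_strength": cfg.coupling_strength,
        "effect_window": None if cfg.coupling_strength == 0 else (t0, t1),
        "covariate_z": z,
    }

    def one_session(session: str, extra: np.ndarray) -> ErpSet:
        data = background[None] + effect + extra + _subject_noise(rng, cfg)
        data -= data.mean(axis=1, keepdims=True)  # enforce average reference exactly
        return ErpSet(data, cfg.sampling_rate, cfg.onset_index, session=session)

    if sessions == 1:
        return one_session("pre", 0.0), ground_truth

    if session_effect_map is None and session_effect_strength:
        session_effect_map = random_scalp_map(cfg.n_electrodes, rng)
    s0, s1 = session_effect_window or cfg.effect_window
    session_term = np.zeros((cfg.n_electrodes, cfg.n_timeframes))
    if session_effect_map is not None and session_effect_strength:
        session_term[:, s0:s1] = session_effect_strength * np.asarray(session_effect_map)[:, None]
        ground_truth["session_effect_map"] = np.asarray(session_effect_map)
        ground_truth["session_effect_window"] = (s0, s1)
    else:
        ground_truth["session_effect_window"] = None
    pre = one_session("pre", 0.0)
    post = one_session("post", session_term[None])
    return pre, post, ground_truth


def simulate_gaze_subject(beta1: float, noise_sd: float, schedule: pd.DataFrame,
                          seed: int, background_share: float = 0.2) -> pd.DataFrame:
    """Simulate one subject's per-trial gaze indices over a Pavlovian schedule.

    The gaze index is ``clip(β1 · cs_value + ε, −1, 1)`` with
    ``ε ~ N(0, noise_sd)``, decomposed into fixation proportions: the
    background receives ``background_share`` of fixation time (shrunk when
    the index magnitude leaves no room) and the CS/US split carries the
    index. Only the difference p(CS) − p(US) is identified.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = schedule["cs_value"].to_numpy(dtype=float)
    index = np.clip(beta1 * values + rng.normal(0.0, noise_sd, size=len(values)), -1.0, 1.0)
    p_bg = np.minimum(background_share, 1.0 - np.abs(index))
    p_cs = (1.0 - p_bg + index) / 2.0
    p_us = (1.0 - p_bg - index) / 2.0
    return pd.DataFrame({
        "trial_index": schedule["trial_index"].to_numpy(),
        "cs_value": values,
        "p_cs": p_cs,
        "p_us": p_us,
        "p_bg": p_bg,
        "valid_fraction": np.ones_like(index),
    })


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_gng_behavior(covariate, schedule: pd.DataFrame, mean_rt: float = 300.0,
                          rt_sd: float = 80.0, commission_rate: float = 0.05,
                          rt_slope: float = 0.0, error_slope: float = 0.0,
                          between_subject_rt_sd: float = 30.0,
                          rate_logit_sd: float = 0.5,
                          rt_shift: float = 120.0, seed: int = 0) -> pd.DataFrame:
    """Simulate a multi-subject Go/NoGo trial table over a schedule.

    Go trials draw a reaction time from a shifted lognormal whose subject
    mean is ``mean_rt + rt_slope · z(β1)`` plus a subject random effect;
    NoGo trials produce a false alarm with probability
    ``logistic(logit(commission_rate) + error_slope · z(β1) + u_s)``.
    With both slopes at 0 behavior is independent of the covariate.

    Returns a tidy table: subject, block, trial_index, trial_type, item_id,
    responded, rt_ms (NaN when no response).
    """
    if not 0.0 <= commission_rate <= 1.0:
        raise ValueError("commission_rate must be a probability")
    beta1 = np.asarray(covariate, dtype=float)
    n_subjects = beta1.size
    z = _zscore(beta1) if n_subjects > 1 and beta1.std(ddof=1) > 0 else np.zeros(n_subjects)
    rng = np.random.default_rng(seed)

    n_trials = len(schedule)
    is_go = (schedule["trial_type"].to_numpy() == "Go")
    subj_mean_rt = mean_rt + rt_slope * z + rng.normal(0.0, between_subject_rt_sd, n_subjects)
    subj_mean_rt = np.maximum(subj_mean_rt, rt_shift + 50.0)
    if commission_rate in (0.0, 1.0):
        fa_prob = np.full(n_subjects, commission_rate)
    else:
        logit = np.log(commission_rate / (1.0 - commission_rate))
        eta = logit + error_slope * z + rng.normal(0.0, rate_logit_sd, n_subjects)
        fa_prob = 1.0 / (1.0 + np.exp(-eta))

    frames = []
    for s in range(n_subjects):
        mu, sigma = _lognormal_params(subj_mean_rt[s] - rt_shift, rt_sd)
        rt = np.full(n_trials, np.nan)
        responded = np.zeros(n_trials, dtype=bool)
        rt[is_go] = rt_shift + rng.lognormal(mu, sigma, is_go.sum())
        responded[is_go] = True
        fa = rng.random((~is_go).sum()) < fa_prob[s]
        responded[~is_go] = fa
        # false alarms are fast impulsive presses
        fa_rt = rt_shift + rng.lognormal(mu, sigma, fa.sum()) * 0.8
        rt[np.flatnonzero(~is_go)[fa]] = fa_rt
        frames.append(pd.DataFrame({
            "subject": s,
            "block": schedule["block"].to_numpy(),
            "trial_index": schedule["trial_index"].to_numpy(),
            "trial_type": schedule["trial_type"].to_numpy(),
            "item_id": schedule["item_id"].to_numpy(),
            "responded": responded,
            "rt_ms": rt,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_liking(n_subjects: int, n_items: int = 57, pre_mean: float = 69.1,
                    pre_sd: float = 14.0, devaluation_dz: float = 0.9,
                    subject_shift_sd: float = 8.0, item_noise_sd: float = 6.0,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate pre/post visual-analogue liking ratings (0-100).

    Half of the items are trained-NoGo; each subject's NoGo items lose a
    subject-level devaluation shift (plus item re-rating noise) at post.
    The shift is calibrated so that the expected paired effect size
    (Cohen's dz on subject-mean trained-NoGo liking) equals
    ``devaluation_dz``: with subject shift spread ``σ_s``, item noise
    ``σ_e`` and m NoGo items, δ = dz · sqrt(σ_s² + 2σ_e²/m).
    """
    if not 0.0 <= pre_mean <= 100.0:
        raise ValueError("pre_mean must lie on the 0-100 VAS scale")
    rng = np.random.default_rng(seed)
    n_nogo = n_items // 2
    categories = np.array(["NoGo"] * n_nogo + ["Go"] * (n_items - n_nogo))
    delta = devaluation_dz * np.sqrt(subject_shift_sd ** 2 + 2 * item_noise_sd ** 2 / n_nogo)
    rows = []
    for s in range(n_subjects):
        true_liking = rng.normal(pre_mean, pre_sd, n_items)
        pre = np.clip(true_liking + rng.normal(0, item_noise_sd, n_items), 0, 100)
        shift = (delta + rng.normal(0.0, subject_shift_sd)) * (categories == "NoGo")
        post = np.clip(true_liking - shift + rng.normal(0, item_noise_sd, n_items), 0, 100)
        rows.append(pd.DataFrame({
            "subject": s,
            "item_id": [f"item{i + 1}" for i in range(n_items)],
            "trained_category": categories,
            "pre": pre,
            "post": post,
        }))
    return pd.concat(rows, ignore_index=True)
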