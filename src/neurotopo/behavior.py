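"""Behavioral indices, exclusion rules, correlation tests with JZS Bayes
factors, positive controls, split-half reliability, and the a-priori power
computation for the correlation design.

The two performance indices of the Go/NoGo task are the commission error
rate (false alarms / NoGo trials) and the mean reaction time of correct
(within-deadline) Go responses. Each index is related to the sign-tracking
bias with a Pearson correlation, reported with a JZS Bayes factor for the
null (stretched-beta prior, scale 1/3, the default of the standard
Bayes-factor software for correlations). BF01 > 3 is read as positive
evidence for the absence of a relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .gaze import mad_outlier_mask
from .schedules import adaptive_rtt

__all__ = [
    "CorrelationReport",
    "GngPerformance",
    "PositiveControls",
    "SplitHalfReliability",
    "bias_performance_correlation",
    "cohens_dz",
    "correlation_power",
    "delta_scores",
    "gng_performance",
    "gng_performance_table",
    "jzs_bf01_correlation",
    "pearson_test",
    "positive_controls",
    "required_n_correlation",
    "spearman_brown",
    "split_half_reliability",
]

#: Participation checks: exclude above these rates at either session.
MAX_FALSE_ALARM_RATE = 0.70
MAX_MISS_RATE = 0.20

DEFAULT_BF_PRIOR_SCALE = 1.0 / 3.0


# ---------------------------------------------------------------------------
# performance indices

@dataclass(frozen=True)
class GngPerformance:
    """Per-subject Go/NoGo performance for one session."""

    subject_id: object
    commission_error_rate: float
    mean_rt_correct: float
    n_go: int
    n_nogo: int
    false_alarm_rate: float
    miss_rate: float
    participation_excluded: bool


def _performance_one(trials: pd.DataFrame, subject_id, rtt) -> GngPerformance:
    is_go = trials["trial_type"].to_numpy() == "Go"
    n_go, n_nogo = int(is_go.sum()), int((~is_go).sum())
    if n_nogo == 0:
        raise ValueError("commission error rate undefined without NoGo trials")
    responded = trials["responded"].to_numpy(dtype=bool)
    rt = trials["rt_ms"].to_numpy(dtype=float)

    hit = np.zeros(len(trials), dtype=bool)
    for _, block in trials.groupby("block"):
        bi = block.index
        go_resp = block.loc[(block["trial_type"] == "Go") & block["responded"]]
        if rtt == "adaptive":
            if len(go_resp) == 0:
                continue
            deadline = adaptive_rtt(go_resp["rt_ms"].to_numpy())
        else:
            deadline = float(rtt)
        within = trials.loc[bi, "rt_ms"].to_numpy() <= deadline
        hit[trials.index.get_indexer(bi)] = (
            (trials.loc[bi, "trial_type"] == "Go").to_numpy()
            & trials.loc[bi, "responded"].to_numpy(dtype=bool) & within
        )

    fa = int((responded & ~is_go).sum())
    fa_rate = fa / n_nogo
    miss_rate = 1.0 - hit.sum() / n_go if n_go else np.nan
    mean_rt = float(rt[hit].mean()) if hit.any() else np.nan
    return GngPerformance(
        subject_id=subject_id,
        commission_error_rate=fa_rate,
        mean_rt_correct=mean_rt,
        n_go=n_go, n_nogo=n_nogo,
        false_alarm_rate=fa_rate,
        miss_rate=float(miss_rate),
        participation_excluded=(fa_rate > MAX_FALSE_ALARM_RATE) or (miss_rate > MAX_MISS_RATE),
    )


def gng_performance(trials: pd.DataFrame, rtt="adaptive",
                    subject_id=None) -> GngPerformance:
    """Reduce one subject's Go/NoGo trial table to performance indices.

    Needs columns ``trial_type`` ('Go'/'NoGo'), ``responded``, ``rt_ms`` and
    ``block``. A Go response is a Hit only if it beats the block deadline
    (``rtt="adaptive"`` recomputes 1.10 × block median RT; a float fixes
    it). A Miss is a Go trial without a Hit — no response or one beyond the
    deadline. The participation check flags false-alarm rates above 70% or
    miss rates above 20%.
    """
    return _performance_one(trials.reset_index(drop=True), subject_id, rtt)


def gng_performance_table(trials: pd.DataFrame, rtt="adaptive") -> pd.DataFrame:
    """Per-subject performance indices for a multi-subject trial table."""
    rows = []
    for sid, sub in trials.groupby("subject"):
        perf = _performance_one(sub.reset_index(drop=True), sid, rtt)
        rows.append(vars(perf))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeltaScores:
    """Post-minus-pre training change in the performance indices."""

    subject_id: object
    d_commission_error_rate: float
    d_mean_rt_correct: float
    direction: str = "post_minus_pre"


def delta_scores(pre: GngPerformance, post: GngPerformance) -> DeltaScores:
    """Training-induced change of each index, computed as post − pre."""
    if pre.subject_id != post.subject_id:
        raise ValueError("pre and post belong to different subjects")
    return DeltaScores(
        subject_id=pre.subject_id,
        d_commission_error_rate=post.commission_error_rate - pre.commission_error_rate,
        d_mean_rt_correct=post.mean_rt_correct - pre.mean_rt_correct,
    )


# ---------------------------------------------------------------------------
# correlation inference

_ALTERNATIVES = {"two_sided": "two-sided", "one_sided_pos": "greater",
                 "one_sided_neg": "less"}


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    t_stat: float
    df: int
    p_value: float
    n: int
    alternative: str
    bf01: float | None = None


def pearson_test(x, y, alternative: str = "two_sided") -> CorrelationReport:
    """Pearson correlation with t-based p-value (df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y, alternative=_ALTERNATIVES[alternative])
    r = float(res.statistic)
    n = x.size
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    return CorrelationReport(r=r, t_stat=float(t), df=n - 2,
                             p_value=float(res.pvalue), n=n, alternative=alternative)


def _log_r_density_shape(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """log f(r | rho, n) up to terms constant in rho (bivariate normal)."""
    rho = np.asarray(rho, dtype=float)
    return ((n - 1) / 2.0 * np.log1p(-rho ** 2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)))


def _stretched_beta_logpdf(rho: np.ndarray, scale: float) -> np.ndarray:
    a = 1.0 / scale
    return ((a - 1.0) * np.log1p(-rho ** 2)
            - special.betaln(a, a) - (2.0 * a - 1.0) * np.log(2.0))


def jzs_bf01_correlation(r: float, n: int, prior_scale: float = DEFAULT_BF_PRIOR_SCALE) -> float:
    """JZS Bayes factor for the null over a correlated alternative.

    The alternative places a stretched symmetric beta prior on ρ over
    (−1, 1) with scale κ (κ=1 uniform; the default κ=1/3 concentrates mass
    near 0, matching the correlation default of the standard Bayes-factor
    software). BF10 is the prior-averaged likelihood ratio of the exact
    bivariate-normal sampling density of r; BF01 is its reciprocal.
    """
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError("r must be finite with |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")

    def integrand(rho):
        return np.exp(_log_r_density_shape(r, rho, n) - _log_r_density_shape(r, 0.0, n)
                      + _stretched_beta_logpdf(rho, prior_scale))

    bf10, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    return 1.0 / bf10


def bias_performance_correlation(performance: pd.DataFrame, bias, index: str,
                                 alternative: str = "one_sided_pos",
                                 prior_scale: float = DEFAULT_BF_PRIOR_SCALE,
                                 mad_k: float = 3.0) -> CorrelationReport:
    """Correlate the sign-tracking bias with one performance index.

    Applies the distribution-outlier rule (3·MAD around the index median)
    before testing, then reports the Pearson correlation with its JZS BF01.
    ``index`` is a column of ``performance`` (e.g. 'commission_error_rate').
    """
    y = performance[index].to_numpy(dtype=float)
    x = np.asarray(bias, dtype=float)
    keep = mad_outlier_mask(y, k=mad_k)
    report = pearson_test(x[keep], y[keep], alternative=alternative)
    bf01 = jzs_bf01_correlation(report.r, report.n, prior_scale)
    return CorrelationReport(**{**vars(report), "bf01": bf01})


def cohens_dz(pre, post) -> float:
    """Paired effect size: mean(pre − post) / sd(pre − post), sample sd.

    Positive values indicate devaluation (pre above post).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of the paired differences")
    return float(diff.mean() / sd)


# ---------------------------------------------------------------------------
# positive controls and reliability

@dataclass(frozen=True)
class PositiveControls:
    """Design-validity checks; report-only, no automatic exclusion."""

    bias_liking_r: float
    bias_liking_ok: bool            # |r| < 0.4
    sd_range_ratio: float
    variability_ok: bool            # sd >= 15% of range
    devaluation_dz: float | None
    devaluation_ok: bool | None     # dz >= 0.4
    degenerate_range: bool = False


def positive_controls(bias, baseline_liking, liking_pre=None, liking_post=None,
                      max_confound_r: float = 0.4, min_sd_range_ratio: float = 0.15,
                      min_devaluation_dz: float = 0.4) -> PositiveControls:
    """Evaluate the three positive controls of the design.

    1. The bias must not be confounded with baseline liking: |r| < 0.4
       (absolute value — confounding matters in either direction).
    2. The bias must vary: sd at least 15% of the observed range (boundary
       inclusive).
    3. The training must have worked: Cohen's dz of pre vs post liking of
       trained-NoGo items at least 0.4 (only when pre/post are supplied).
    """
    bias = np.asarray(bias, dtype=float)
    r = pearson_test(bias, baseline_liking).r
    rng_span = float(bias.max() - bias.min())
    degenerate = rng_span == 0.0
    ratio = np.nan if degenerate else float(bias.std(ddof=1) / rng_span)
    dz = ok_dz = None
    if liking_pre is not None and liking_post is not None:
        dz = cohens_dz(liking_pre, liking_post)
        ok_dz = dz >= min_devaluation_dz
    return PositiveControls(
        bias_liking_r=r, bias_liking_ok=abs(r) < max_confound_r,
        sd_range_ratio=ratio,
        variability_ok=(not degenerate) and ratio >= min_sd_range_ratio,
        devaluation_dz=dz, devaluation_ok=ok_dz,
        degenerate_range=degenerate,
    )


def spearman_brown(r: float) -> float:
    """Spearman-Brown step-up of a half-test correlation: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


@dataclass(frozen=True)
class SplitHalfReliability:
    r_halves: float
    corrected: float
    index: str


def split_half_reliability(trials: pd.DataFrame, index: str = "rt",
                           rtt="adaptive") -> SplitHalfReliability:
    """Odd/even split-half reliability of a performance index.

    Each subject's trials are split by parity of ``trial_index``; the index
    ('rt' for mean correct-response time, 'commission' for the commission
    error rate) is computed per half, correlated across subjects, and
    Spearman-Brown corrected.
    """
    if index not in ("rt", "commission"):
        raise ValueError("index must be 'rt' or 'commission'")
    halves: dict[int, list[float]] = {0: [], 1: []}
    for _, sub in trials.groupby("subject"):
        for parity in (0, 1):
            half = sub[sub["trial_index"] % 2 == parity]
            if len(half) < 4:
                raise ValueError("need at least 4 trials per subject per half")
            perf = _performance_one(half.reset_index(drop=True), None, rtt)
            halves[parity].append(perf.mean_rt_correct if index == "rt"
                                  else perf.commission_error_rate)
    r = pearson_test(halves[0], halves[1]).r
    return SplitHalfReliability(r_halves=r, corrected=spearman_brown(r), index=index)


# ---------------------------------------------------------------------------
# a-priori power

def _exact_r_logpdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return (np.log(n - 2) + special.gammaln(n - 1)
            + (n - 1) / 2.0 * np.log1p(-rho ** 2)
            + (n - 4) / 2.0 * np.log1p(-r ** 2)
            - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)))


def correlation_power(n: int, rho: float, alpha: float = 0.05,
                      one_sided: bool = True, method: str = "nct") -> float:
    """Power of the test of a Pearson correlation against zero.

    ``method="nct"`` evaluates the noncentral-t approximation with
    noncentrality ρ√n/√(1−ρ²) (the evaluation behind the common power
    software); ``method="exact"`` integrates the exact bivariate-normal
    sampling density of r beyond the critical value. The two differ by a
    few points of power at moderate n (exact is slightly lower for ρ > 0).
    """
    if n < 4:
        return 0.0
    df = n - 2
    tail = alpha if one_sided else alpha / 2.0
    t_crit = stats.t.ppf(1.0 - tail, df)
    if method == "nct":
        nc = rho / np.sqrt(1.0 - rho ** 2) * np.sqrt(n)
        power = 1.0 - stats.nct.cdf(t_crit, df, nc)
        if not one_sided:
            power += stats.nct.cdf(-t_crit, df, nc)
        return float(power)
    if method == "exact":
        r_crit = t_crit / np.sqrt(df + t_crit ** 2)
        upper, _ = integrate.quad(lambda r: np.exp(_exact_r_logpdf(r, rho, n)), r_crit, 1.0)
        if one_sided:
            return float(upper)
        lower, _ = integrate.quad(lambda r: np.exp(_exact_r_logpdf(r, rho, n)), -1.0, -r_crit)
        return float(upper + lower)
    raise ValueError("method must be 'nct' or 'exact'")


def required_n_correlation(rho: float = 0.4, alpha: float = 0.05,
                           power: float = 0.90, one_sided: bool = True,
                           method: str = "nct", n_max: int = 100000) -> int:
    """Smallest n whose correlation-test power reaches the target.

    Defaults reproduce the registered sampling plan: a one-sided test of
    ρ = 0.4 at α = 0.05 needs 47 participants for 90% power under the
    noncentral-t evaluation.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(4, n_max + 1):
        if correlation_power(n, rho, alpha, one_sided, method) >= power:
            return n
    raise ValueError("target power unattainable within n_max")
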