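"""Topographic permutation statistics for multi-subject ERPs.

The engine implements the electrical-neuroimaging tests used to relate ERP
scalp topographies to a subject-level variable:

* **TANCOVA** (topographic analysis of covariance): at every timeframe the
  covariance map between the z-scored covariate and the subject maps is
  formed, and its global field power (GFP) is the test statistic. The null
  distribution comes from shuffling the covariate across subjects while
  keeping the ERP data fixed (5,000 randomizations by default).
* **TANOVA for a within-subject Session factor**: the statistic is the GFP
  of the mean pre/post difference map; the null flips the sign of each
  subject's difference map (session labels are exchangeable within
  subject).
* **Duration-based multiple-comparison control**: a run of consecutive
  significant timeframes only counts as a cluster if it is at least as
  long as the shortest run that occurs with probability ``global_alpha``
  under the shuffled data; the fixed fallback used when no permutation
  series are available is 12 timeframes (~12 ms at 1024 Hz).

p-values use the add-one convention, ``(1 + #{perm >= obs}) / (n_perm + 1)``,
with ties counted as exceedances. In exhaustive mode every distinct
permutation (or sign-flip pattern) is enumerated exactly once — the
identity included — and the p-value is the plain exceedance fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .containers import ErpSet
from .erp import gfp_series

__all__ = [
    "TopoTestResult",
    "DEFAULT_N_PERMUTATIONS",
    "FALLBACK_DURATION_TF",
    "covariance_map",
    "duration_threshold",
    "find_clusters",
    "tancova_timewise",
    "tancova_session_covariate",
    "tanova_session",
]

DEFAULT_N_PERMUTATIONS = 5000

#: Documented fixed fallback for the minimal cluster duration (timeframes).
FALLBACK_DURATION_TF = 12


@dataclass
class TopoTestResult:
    """Outcome of a timewise topographic permutation test."""

    statistic_series: np.ndarray
    p_series: np.ndarray
    n_permutations: int
    alpha: float
    duration_threshold_tf: int
    clusters: list[tuple[int, int]]
    clusters_ms: list[tuple[float, float]]
    covariance_maps: np.ndarray | None = None
    seed: int | None = None
    exhaustive: bool = False
    permutations: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return bool(self.clusters)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("covariate has zero variance")
    return (x - x.mean()) / sd


def covariance_map(maps_at_tf: np.ndarray, covariate) -> np.ndarray:
    """Covariance map between subject scalp maps and a covariate at one TF.

    ``c_e = (1/N) Σ_s z(x_s) (v_{s,e} − v̄_e)`` with the covariate z-scored
    and the maps mean-centered across subjects. Linear in the data; flipping
    the covariate's sign flips the map. Units: µV per covariate SD.
    """
    v = np.asarray(maps_at_tf, dtype=float)
    if v.ndim != 2:
        raise ValueError("maps_at_tf must be (subjects, electrodes)")
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    z = _zscore(covariate)
    if z.shape != (n,):
        raise ValueError("covariate length must match the number of subjects")
    return z @ (v - v.mean(axis=0)) / n


def _data_array(erps) -> np.ndarray:
    return erps.data if isinstance(erps, ErpSet) else np.asarray(erps, dtype=float)


def _weighted_stats(weights: np.ndarray, centered: np.ndarray) -> np.ndarray:
    """GFP-of-weighted-mean statistic series for each weight row.

    ``weights`` is (P, S); ``centered`` is (S, E, T) already subject-mean
    centered. Returns (P, T).
    """
    S, E, T = centered.shape
    flat = centered.reshape(S, E * T)
    maps = (weights @ flat).reshape(-1, E, T) / S
    return gfp_series(maps)


def _permutation_rows(z: np.ndarray, n_permutations: int, rng: np.random.Generator,
                      exhaustive: bool) -> np.ndarray:
    n = z.size
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        return z[perms]
    rows = np.empty((n_permutations, n))
    for i in range(n_permutations):
        rows[i] = z[rng.permutation(n)]
    return rows


def _sign_flip_rows(n_subjects: int, n_permutations: int, rng: np.random.Generator,
                    exhaustive: bool) -> np.ndarray:
    if exhaustive:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
    return rng.choice([1.0, -1.0], size=(n_permutations, n_subjects))


def _p_series(obs: np.ndarray, perm: np.ndarray, exhaustive: bool) -> np.ndarray:
    exceed = (perm >= obs[None, :]).sum(axis=0)
    if exhaustive:
        return exceed / perm.shape[0]
    return (1.0 + exceed) / (perm.shape[0] + 1.0)


def _assemble(erps, obs_stats, p, perm_stats, alpha, duration, seed, exhaustive,
              cov_maps, weight_rows) -> TopoTestResult:
    if duration == "auto":
        min_len = duration_threshold(perm_stats, alpha=alpha)
    elif duration == "fixed":
        min_len = FALLBACK_DURATION_TF
    else:
        min_len = int(duration)
    clusters = find_clusters(p, alpha, min_len)
    if isinstance(erps, ErpSet):
        sfreq, onset = erps.sampling_rate, erps.onset_index
    else:
        sfreq, onset = None, 0
    clusters_ms = []
    if sfreq is not None:
        for a, b in clusters:
            clusters_ms.append(((a - onset) * 1000.0 / sfreq, (b - onset) * 1000.0 / sfreq))
    return TopoTestResult(
        statistic_series=obs_stats, p_series=p,
        n_permutations=perm_stats.shape[0], alpha=alpha,
        duration_threshold_tf=min_len, clusters=clusters, clusters_ms=clusters_ms,
        covariance_maps=cov_maps, seed=seed, exhaustive=exhaustive,
        permutations=weight_rows,
    )


def tancova_timewise(erps, covariate, n_permutations: int = DEFAULT_N_PERMUTATIONS,
                     alpha: float = 0.05, duration="auto", seed: int | None = None,
                     exhaustive: bool = False) -> TopoTestResult:
    """Timewise TANCOVA of subject ERPs against a between-subject covariate.

    At each timeframe the statistic is the GFP of the covariance map; the
    null shuffles covariate values across subjects with the ERP data fixed.
    ``duration`` selects the multiple-comparison control: ``"auto"``
    calibrates the minimal cluster length from the permutation series,
    ``"fixed"`` uses the 12-TF fallback, an integer is taken as-is.
    ``exhaustive=True`` enumerates all n! covariate orderings (small n only)
    and yields exact enumeration p-values.
    """
    data = _data_array(erps)
    S = data.shape[0]
    z = _zscore(covariate)
    if z.shape != (S,):
        raise ValueError("one covariate value per subject is required")
    if not exhaustive and n_permutations < 100:
        import warnings
        warnings.warn("fewer than 100 permutations gives a coarse null", RuntimeWarning)
    if exhaustive and math.factorial(S) > 50000:
        raise ValueError("exhaustive enumeration is limited to small samples")
    rng = np.random.default_rng(seed)
    centered = data - data.mean(axis=0, keepdims=True)
    rows = _permutation_rows(z, n_permutations, rng, exhaustive)
    if exhaustive:
        # place the identity ordering first so the observed statistic shares
        # its floating-point path with the enumerated rows
        ident = np.flatnonzero((rows == z[None, :]).all(axis=1))[0]
        rows[[0, ident]] = rows[[ident, 0]]
    perm_stats = _weighted_stats(rows, centered)
    obs_stats = perm_stats[0] if exhaustive else _weighted_stats(z[None, :], centered)[0]
    p = _p_series(obs_stats, perm_stats, exhaustive)
    cov_maps = (z @ centered.reshape(S, -1)).reshape(data.shape[1:]) / S
    return _assemble(erps, obs_stats, p, perm_stats, alpha, duration, seed,
                     exhaustive, cov_maps, rows)


def tanova_session(pre, post, n_permutations: int = DEFAULT_N_PERMUTATIONS,
                   alpha: float = 0.05, duration="auto", seed: int | None = None,
                   exhaustive: bool = False) -> TopoTestResult:
    """Within-subject Session (pre vs post) topographic permutation test.

    Works on per-subject difference maps ``d_s = post − pre``; the statistic
    is the GFP of their mean, and the null randomly flips the sign of each
    subject's difference map. ``exhaustive=True`` enumerates all 2^S flip
    patterns.
    """
    dpre, dpost = _data_array(pre), _data_array(post)
    if dpre.shape != dpost.shape:
        raise ValueError("pre and post must hold the same subjects/dimensions")
    diffs = dpost - dpre
    S = diffs.shape[0]
    if exhaustive and S > 16:
        raise ValueError("exhaustive sign-flip enumeration is limited to small samples")
    rng = np.random.default_rng(seed)
    rows = _sign_flip_rows(S, n_permutations, rng, exhaustive)
    if exhaustive:
        ident = np.flatnonzero((rows == 1.0).all(axis=1))[0]
        rows[[0, ident]] = rows[[ident, 0]]
    # statistic: GFP of the (signed) mean difference map; no subject centering
    flat = diffs.reshape(S, -1)
    perm_maps = (rows @ flat).reshape(-1, *diffs.shape[1:]) / S
    perm_stats = gfp_series(perm_maps)
    if exhaustive:
        obs_stats = perm_stats[0]
    else:
        obs_stats = gfp_series(diffs.mean(axis=0))
    p = _p_series(obs_stats, perm_stats, exhaustive)
    mean_diff = diffs.mean(axis=0)
    return _assemble(pre if isinstance(pre, ErpSet) else None, obs_stats, p,
                     perm_stats, alpha, duration, seed, exhaustive, mean_diff, rows)


def tancova_session_covariate(pre, post, covariate,
                              n_permutations: int = DEFAULT_N_PERMUTATIONS,
                              alpha: float = 0.05, duration="auto",
                              seed: int | None = None,
                              exhaustive: bool = False) -> TopoTestResult:
    """Covariate × Session TANCOVA: covariance of the covariate with the
    per-subject pre/post difference maps, permuting the covariate."""
    dpre, dpost = _data_array(pre), _data_array(post)
    if dpre.shape != dpost.shape:
        raise ValueError("pre and post must hold the same subjects/dimensions")
    diffs = dpost - dpre
    template = pre if isinstance(pre, ErpSet) else None
    result = tancova_timewise(diffs, covariate, n_permutations=n_permutations,
                              alpha=alpha, duration=duration, seed=seed,
                              exhaustive=exhaustive)
    if template is not None:
        onset, sfreq = template.onset_index, template.sampling_rate
        result.clusters_ms = [((a - onset) * 1000.0 / sfreq, (b - onset) * 1000.0 / sfreq)
                              for a, b in result.clusters]
    return result


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Longest True-run per row of a (P, T) boolean array."""
    P, T = flags.shape
    out = np.zeros(P, dtype=int)
    cur = np.zeros(P, dtype=int)
    for t in range(T):
        cur = np.where(flags[:, t], cur + 1, 0)
        out = np.maximum(out, cur)
    return out


def duration_threshold(permutation_stats: np.ndarray, alpha: float = 0.05,
                       global_alpha: float = 0.05) -> int:
    """Minimal cluster duration calibrated from the permutation null.

    Each permutation's statistic series is converted to a pseudo-p series
    against the whole ensemble; the threshold is the smallest run length L
    such that at most ``global_alpha`` of permutations contain a run of
    L or more consecutive pseudo-p < ``alpha`` timeframes. Controls the
    family-wise error over time at ``global_alpha``. Capped at the series
    length when even whole-series runs are too frequent (perfectly
    autocorrelated degenerate nulls).
    """
    perm = np.asarray(permutation_stats, dtype=float)
    if perm.ndim != 2 or perm.shape[0] < 100:
        raise ValueError("need >= 100 permutation statistic series")
    P, T = perm.shape
    # pseudo-p of each permutation at each TF: fraction of ensemble >= it
    ranks = _sstats.rankdata(perm, method="min", axis=0)
    pseudo_p = (P - ranks + 1) / P
    runs = _run_lengths(pseudo_p < alpha)
    max_allowed = int(np.floor(global_alpha * P))
    # smallest L with #{runs >= L} <= global_alpha * P
    counts = np.bincount(runs, minlength=T + 2)
    n_ge = np.cumsum(counts[::-1])[::-1]  # n_ge[L] = #{runs >= L}
    for L in range(1, T + 1):
        if n_ge[L] <= max_allowed:
            return L
    return T


def find_clusters(p_series: np.ndarray, alpha: float, min_length: int) -> list[tuple[int, int]]:
    """Maximal runs of p < alpha of at least ``min_length`` timeframes.

    Intervals are half-open ``[start, stop)``. The comparison is strict:
    p exactly equal to alpha is not significant.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    sig = np.asarray(p_series) < alpha
    clusters = []
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_length:
                clusters.append((start, i))
            start = None
    return clusters
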