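"""Autocorrelation-robust monotone-trend tests and rank cross-correlations.

Long ecological time series are serially correlated, which makes the
normal-approximation Mann-Kendall test anticonservative.  The approach
here keeps the classical Mann-Kendall machinery — the Kendall score
S = sum_{i<j} sign(x_j - x_i), its tie-corrected variance, the
continuity-corrected normal deviate Z, Kendall's tau-b and Sen's
median-of-pairwise-slopes estimate — but replaces the normal null with a
block-bootstrap null: the observed series is cut into contiguous
non-overlapping blocks (default 3 years), the blocks are resampled with
replacement, and S is recomputed per replicate.  Resampling block order
destroys any trend while within-block resampling preserves short-range
autocorrelation, so the resulting two-sided p-value keeps its nominal size
on autocorrelated but trend-free series.

Cross-correlations between year-indexed series use Spearman's rho on
pairwise-complete years with a t-approximation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MKStats",
    "TrendResult",
    "SpearmanResult",
    "CorrelationMatrixResult",
    "mk_statistics",
    "mk_normal_p",
    "sen_slope",
    "block_bootstrap_mk",
    "spearman_pair",
    "correlation_matrix",
]

BLOCK_LENGTH_DEFAULT = 3
REPLICATES_DEFAULT = 2000
MIN_MK_N = 4
MIN_SPEARMAN_N = 5


@dataclass(frozen=True)
class MKStats:
    s: int
    var_s: float
    z: float
    tau: float
    n: int
    flag: str = ""


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall trend test with a block-bootstrap null."""

    s: int
    var_s: float
    z: float
    tau: float
    sen_slope: float
    p_boot: float
    block_length: int
    replicates: int
    seed: int
    n: int
    flag: str = ""


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    flag: str = ""


@dataclass(frozen=True)
class CorrelationMatrixResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def _clean(series, years=None) -> tuple[np.ndarray, np.ndarray]:
    """Values and time points with missing entries dropped, time order kept."""
    if isinstance(series, pd.Series):
        x = series.to_numpy(dtype=float)
        t = series.index.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
        t = np.arange(len(x), dtype=float) if years is None else np.asarray(years, dtype=float)
    keep = np.isfinite(x)
    return x[keep], t[keep]


def _s_statistic_batch(X: np.ndarray) -> np.ndarray:
    """Kendall S for each row of an (m, n) matrix, vectorized."""
    diff = np.sign(X[:, None, :] - X[:, :, None])  # (m, n, n); diff[., i, j] = sign(x_j - x_i)
    iu = np.triu_indices(X.shape[1], k=1)
    return diff[:, iu[0], iu[1]].sum(axis=1)


def mk_statistics(series, years=None) -> MKStats:
    """Mann-Kendall S, tie-corrected variance, continuity-corrected Z, tau-b.

    Missing values are dropped; ranks are taken in time order so gap years
    are allowed.  An all-tied series returns S = 0, Z = 0, tau = 0 with the
    flag ``"all tied"``.
    """
    x, _t = _clean(series, years)
    n = len(x)
    if n < MIN_MK_N:
        raise ValueError(f"need at least {MIN_MK_N} non-missing values, got {n}")
    s = int(_s_statistic_batch(x[None, :])[0])
    # tie-group correction to Var(S)
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    flag = ""
    if np.all(x == x[0]):
        return MKStats(0, 0.0, 0.0, 0.0, n, "all tied")
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    n0 = n * (n - 1) / 2.0
    ties_y = float(np.sum(counts * (counts - 1) / 2.0))
    tau = s / np.sqrt(n0 * (n0 - ties_y))  # tau-b; time points are untied
    return MKStats(s, float(var_s), float(z), float(tau), n, flag)


def mk_normal_p(series, years=None) -> float:
    """Two-sided p from the unmodified normal approximation (no bootstrap)."""
    mk = mk_statistics(series, years)
    return float(2.0 * stats.norm.sf(abs(mk.z)))


def sen_slope(series, years=None) -> float:
    """Sen's slope: median of all pairwise slopes over calendar-year spacing."""
    x, t = _clean(series, years)
    if len(x) < 2:
        raise ValueError("need at least 2 non-missing values")
    i, j = np.triu_indices(len(x), k=1)
    slopes = (x[j] - x[i]) / (t[j] - t[i])
    return float(np.median(slopes))


def block_bootstrap_mk(
    series,
    block_length: int = BLOCK_LENGTH_DEFAULT,
    replicates: int = REPLICATES_DEFAULT,
    seed: int = 0,
    years=None,
) -> TrendResult:
    """Mann-Kendall test with a non-overlapping block-bootstrap null.

    The observed sequence (missing years dropped) is truncated to a
    multiple of ``block_length``, cut into contiguous non-overlapping
    blocks, and ``replicates`` null series are built by drawing blocks with
    replacement.  Both the observed score and the replicate scores are
    computed on the truncated sequence so they share one sample size;
    p_boot = (1 + #{|S*| >= |S_obs|}) / (replicates + 1), two-sided.
    The reported S, Var(S), Z, tau and Sen slope describe the full observed
    series.  Deterministic for a fixed seed.
    """
    x, t = _clean(series, years)
    n = len(x)
    if n < 2 * block_length:
        raise ValueError(
            f"series too short for block bootstrap: need >= {2 * block_length} "
            f"non-missing values (2 blocks of {block_length}), got {n}"
        )
    mk = mk_statistics(x, t)
    slope = sen_slope(x, t)

    n_blocks = n // block_length
    m = n_blocks * block_length
    trunc = x[:m]
    blocks = trunc.reshape(n_blocks, block_length)
    s_obs = int(_s_statistic_batch(trunc[None, :])[0])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_blocks, size=(replicates, n_blocks))
    # chunk the (replicates, m, m) sign tensor to bound memory
    s_star = np.empty(replicates, dtype=np.int64)
    chunk = max(1, int(4e7 // (m * m)))
    for start in range(0, replicates, chunk):
        sel = idx[start:start + chunk]
        sims = blocks[sel].reshape(len(sel), m)
        s_star[start:start + len(sel)] = _s_statistic_batch(sims)
    p_boot = (1.0 + np.count_nonzero(np.abs(s_star) >= abs(s_obs))) / (replicates + 1.0)
    return TrendResult(
        s=mk.s, var_s=mk.var_s, z=mk.z, tau=mk.tau, sen_slope=slope,
        p_boot=float(p_boot), block_length=block_length, replicates=replicates,
        seed=int(seed), n=n, flag=mk.flag,
    )


def spearman_pair(x, y) -> SpearmanResult:
    """Spearman's rho on pairwise-complete observations.

    Ties receive average ranks; the two-sided p-value uses the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2)).  A perfect correlation
    reports p at the smallest positive float rather than zero; fewer than
    5 complete pairs, or a zero-rank-variance input, yields a missing
    result with a reason.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        df = pd.concat([x, y], axis=1, join="inner")
        xv = df.iloc[:, 0].to_numpy(dtype=float)
        yv = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    n = len(xv)
    if n < MIN_SPEARMAN_N:
        return SpearmanResult(float("nan"), float("nan"), n, "insufficient overlap")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return SpearmanResult(float("nan"), float("nan"), n, "zero rank variance")
    rho, p = stats.spearmanr(xv, yv)
    if np.isclose(abs(rho), 1.0, rtol=0.0, atol=1e-12):
        rho = float(np.sign(rho))
        p = np.finfo(float).tiny
    return SpearmanResult(float(rho), float(p), n)


def correlation_matrix(table: pd.DataFrame, include_year: bool = True) -> CorrelationMatrixResult:
    """Pairwise Spearman correlations over a year-indexed table of series.

    Missing years are deleted pairwise, so each cell carries its own
    overlap count.  With ``include_year`` a "Year" pseudo-series is added
    so each indicator's rank correlation with time appears as a row.
    """
    if table.shape[1] < 2 and not include_year:
        raise ValueError("need at least 2 series")
    df = table.copy()
    if include_year:
        df.insert(0, "Year", df.index.to_numpy(dtype=float))
    cols = list(df.columns)
    k = len(cols)
    rho = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            if i == j:
                cnt = int(df[a].notna().sum())
                rho.loc[a, b], p.loc[a, b], n.loc[a, b] = 1.0, np.finfo(float).tiny, cnt
                continue
            res = spearman_pair(df[a], df[b])
            rho.loc[a, b] = rho.loc[b, a] = res.rho
            p.loc[a, b] = p.loc[b, a] = res.p
            n.loc[a, b] = n.loc[b, a] = res.n
    return CorrelationMatrixResult(rho, p, n)
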