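"""Per-year life-history indicators for a surveyed fish stock.

The central estimator is the logistic maturity ogive,

    log(p / (1 - p)) = alpha + beta * L,

fitted by Newton iteration on the Bernoulli log-likelihood of individual
maturity-at-length observations; L50 = -alpha/beta is the length at which
half the population is mature, with a delta-method standard error.  A fit
is *accepted* only when it converged and both Wald p-values are below the
acceptance level (default 0.05); the annual L50 is the arithmetic mean of
accepted per-subdivision fits.

Around it sit the standard length-based stock indicators:

* Fulton's condition factor CF = 100*W/L^3 (W in g, L in cm), averaged per
  (year, subdivision) over the 41-60 cm interval when more than five
  records are available;
* LeCren's relative condition K_i = W_i / (a*L_i^b), with (a, b) from an
  ordinary least-squares fit of log W on log L over 20-100 cm fish pooled
  across years;
* the length diversity index LDI (Shannon-Wiener entropy of the annual
  1-cm length-frequency distribution above a 20 cm minimum length);
* L95, the 95th percentile of the length distribution of fish >= 20 cm;
* catch-per-recruit CPR_i = Catch_i / REC_{i-4} in grams per recruit;
* total mortality Z46 = F46 + M46 (M46 conventionally 0.2 before 1991 when
  unreported) and the exploitation rate ER = F46/Z46.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "OgiveFit",
    "LengthWeightFit",
    "fit_ogive",
    "annual_l50",
    "fulton_cf",
    "annual_cf",
    "fit_length_weight",
    "lecren_k",
    "ldi",
    "l95",
    "annual_ldi",
    "annual_l95",
    "catch_per_recruit",
    "total_mortality",
    "exploitation_rate",
]

L_MIN_DEFAULT = 20.0  # cm; minimum length for size-structure indicators
CF_INTERVAL = (41.0, 60.0)  # cm; Fulton CF sampling interval
CF_MIN_RECORDS = 5  # strict: need count > 5
LW_BOUNDS = (20.0, 100.0)  # cm; length-weight fitting interval
OGIVE_MIN_N = 20
OGIVE_TOL = 1e-10
OGIVE_MAX_ITER = 100


@dataclass(frozen=True)
class OgiveFit:
    """A fitted logistic maturity ogive.

    ``accepted`` implies ``converged`` and both Wald p-values below the
    acceptance level with a rising (beta > 0) ogive.  ``reason`` explains a
    failed or rejected fit.
    """

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    p_alpha: float
    p_beta: float
    n_immature: int
    n_mature: int
    l50: float
    l50_se: float
    converged: bool
    accepted: bool
    reason: str = ""

    @property
    def n(self) -> int:
        return self.n_immature + self.n_mature


@dataclass(frozen=True)
class LengthWeightFit:
    """Allometric length-weight relationship W = a * L^b fitted on log scale."""

    a: float
    b: float
    se_log_a: float
    se_b: float
    n: int
    r_squared: float

    def predict(self, length):
        return self.a * np.asarray(length, dtype=float) ** self.b


def _no_fit(n_imm: int, n_mat: int, reason: str) -> OgiveFit:
    nan = float("nan")
    return OgiveFit(nan, nan, nan, nan, nan, nan, n_imm, n_mat, nan, nan,
                    converged=False, accepted=False, reason=reason)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(1+e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_ogive(
    length,
    mature,
    min_n: int = OGIVE_MIN_N,
    alpha_level: float = 0.05,
    acceptance: str = "both",
) -> OgiveFit:
    """Maximum-likelihood logistic regression of maturity on length.

    Newton iteration on the Bernoulli log-likelihood with step-halving;
    converged when successive log-likelihood changes fall below 1e-10
    (at most 100 iterations).  Quasi-separation (diverging |beta| or
    standard errors) is detected and reported as non-convergence.

    ``acceptance`` is ``"both"`` (both Wald p-values < alpha_level, the
    default) or ``"slope"`` (slope only).
    """
    length = np.asarray(length, dtype=float)
    y = np.asarray(mature, dtype=float)
    n_mat = int(y.sum())
    n_imm = int(len(y) - n_mat)
    if len(y) < min_n:
        return _no_fit(n_imm, n_mat, f"fewer than {min_n} records")
    if n_imm == 0 or n_mat == 0:
        return _no_fit(n_imm, n_mat, "single maturity class")

    X = np.column_stack([np.ones_like(length), length])
    b = np.zeros(2)
    ll = _bernoulli_loglik(X @ b, y)
    converged = False
    for _ in range(OGIVE_MAX_ITER):
        eta = X @ b
        p = expit(eta)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return _no_fit(n_imm, n_mat, "singular information matrix")
        # step-halving to guarantee likelihood ascent
        new_ll = -np.inf
        for _half in range(30):
            cand = b + step
            new_ll = _bernoulli_loglik(X @ cand, y)
            if new_ll >= ll - 1e-14:
                break
            step = step / 2.0
        b = b + step
        if not np.all(np.isfinite(b)) or abs(b[1]) > 1e3:
            return _no_fit(n_imm, n_mat, "quasi-separation (diverging slope)")
        if abs(new_ll - ll) < OGIVE_TOL:
            converged = True
            ll = new_ll
            break
        ll = new_ll

    eta = X @ b
    p = expit(eta)
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return _no_fit(n_imm, n_mat, "singular information matrix")
    se = np.sqrt(np.diag(cov))
    alpha_hat, beta_hat = float(b[0]), float(b[1])
    se_a, se_b = float(se[0]), float(se[1])
    if not np.all(np.isfinite(se)) or se_b > 1e3:
        return _no_fit(n_imm, n_mat, "quasi-separation (diverging standard error)")
    z_a = alpha_hat / se_a
    z_b = beta_hat / se_b
    p_a = float(2.0 * stats.norm.sf(abs(z_a)))
    p_b = float(2.0 * stats.norm.sf(abs(z_b)))

    if beta_hat != 0:
        l50 = -alpha_hat / beta_hat
        # delta method on g(alpha, beta) = -alpha/beta
        grad = np.array([-1.0 / beta_hat, alpha_hat / beta_hat**2])
        l50_var = float(grad @ cov @ grad)
        l50_se = float(np.sqrt(l50_var)) if l50_var >= 0 else float("nan")
    else:
        l50, l50_se = float("nan"), float("nan")

    reason = ""
    if not converged:
        reason = "did not converge"
    elif beta_hat <= 0:
        reason = "non-increasing ogive (beta <= 0)"
    elif acceptance == "both" and max(p_a, p_b) >= alpha_level:
        reason = f"Wald p >= {alpha_level}"
    elif acceptance == "slope" and p_b >= alpha_level:
        reason = f"slope Wald p >= {alpha_level}"
    accepted = reason == ""
    return OgiveFit(alpha_hat, beta_hat, se_a, se_b, p_a, p_b, n_imm, n_mat,
                    float(l50), l50_se, converged, accepted, reason)


def annual_l50(
    records: pd.DataFrame,
    sds=None,
    years=None,
    min_n: int = OGIVE_MIN_N,
    alpha_level: float = 0.05,
    acceptance: str = "both",
) -> tuple[pd.DataFrame, list]:
    """Annual L50 as the arithmetic mean of accepted per-subdivision fits.

    ``records`` must carry ``year``, ``sd``, ``length_cm`` and a
    ``maturity_status`` column (already coded and filtered to the spawning
    window); rows coded ``excluded`` are dropped here.  Returns the annual
    series (year-indexed ``value``, ``n`` accepted fits, ``flag``) and an
    audit list of (year, sd, OgiveFit) for every attempted fit.
    """
    df = records[records["maturity_status"].isin(["immature", "mature"])]
    if sds is not None:
        df = df[df["sd"].isin(set(int(s) for s in sds))]
    if years is None:
        years = sorted(df["year"].unique())
    audit = []
    rows = []
    for year in years:
        sub = df[df["year"] == year]
        accepted = []
        for sd, grp in sub.groupby("sd"):
            fit = fit_ogive(
                grp["length_cm"].to_numpy(),
                (grp["maturity_status"] == "mature").to_numpy(),
                min_n=min_n, alpha_level=alpha_level, acceptance=acceptance,
            )
            audit.append((int(year), int(sd), fit))
            if fit.accepted:
                accepted.append(fit.l50)
        if accepted:
            rows.append((int(year), float(np.mean(accepted)), len(accepted), "ok"))
        else:
            rows.append((int(year), float("nan"), 0, "no accepted fits"))
    out = pd.DataFrame(rows, columns=["year", "value", "n", "flag"]).set_index("year")
    return out, audit


def fulton_cf(weight, length):
    """Fulton's condition factor 100*W/L^3 (W in g, L in cm)."""
    weight = np.asarray(weight, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(weight <= 0) or np.any(length <= 0):
        raise ValueError("weight and length must be positive")
    out = 100.0 * weight / length**3
    return out if out.ndim else float(out)


def annual_cf(
    records: pd.DataFrame,
    sds=None,
    years=None,
    interval=CF_INTERVAL,
    min_records: int = CF_MIN_RECORDS,
) -> pd.DataFrame:
    """Annual Fulton CF: per-(year, SD) means over the 41-60 cm interval.

    A (year, SD) cell contributes only when its record count exceeds
    ``min_records`` (strictly); the annual value is the arithmetic mean over
    contributing subdivisions, mirroring the annual L50 aggregation.
    """
    lo, hi = interval
    df = records.dropna(subset=["weight_g"])
    df = df[(df["length_cm"] >= lo) & (df["length_cm"] <= hi)]
    if sds is not None:
        df = df[df["sd"].isin(set(int(s) for s in sds))]
    if years is None:
        years = sorted(df["year"].unique())
    rows = []
    for year in years:
        sub = df[df["year"] == year]
        sd_means = []
        for _sd, grp in sub.groupby("sd"):
            if len(grp) > min_records:
                sd_means.append(float(np.mean(fulton_cf(grp["weight_g"], grp["length_cm"]))))
        if sd_means:
            rows.append((int(year), float(np.mean(sd_means)), len(sd_means), "ok"))
        else:
            rows.append((int(year), float("nan"), 0, "below threshold"))
    return pd.DataFrame(rows, columns=["year", "value", "n", "flag"]).set_index("year")


def fit_length_weight(records: pd.DataFrame, bounds=LW_BOUNDS, min_n: int = 10) -> LengthWeightFit:
    """OLS fit of log W = log a + b log L (natural logs), pooled over years.

    Only fish with recorded weight and 20 <= L <= 100 cm enter the fit; the
    back-transformed coefficient ``a`` is reported alongside ``b`` and the
    log-scale R^2.
    """
    lo, hi = bounds
    df = records.dropna(subset=["weight_g"])
    df = df[(df["length_cm"] >= lo) & (df["length_cm"] <= hi) & (df["weight_g"] > 0)]
    n = len(df)
    if n < min_n:
        raise ValueError(f"need at least {min_n} usable records in {lo}-{hi} cm, got {n}")
    x = np.log(df["length_cm"].to_numpy(dtype=float))
    y = np.log(df["weight_g"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if n > 2:
        s2 = float(resid @ resid) / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([np.nan, np.nan])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return LengthWeightFit(
        a=float(np.exp(coef[0])), b=float(coef[1]),
        se_log_a=float(se[0]), se_b=float(se[1]), n=n, r_squared=r2,
    )


def lecren_k(weight, length, fit: LengthWeightFit):
    """LeCren's relative condition: observed over predicted weight.

    Defined for any positive length (values outside the 20-100 cm fitting
    interval are legitimate but extrapolated)."""
    weight = np.asarray(weight, dtype=float)
    out = weight / fit.predict(length)
    return out if out.ndim else float(out)


def ldi(counts, l_min: float = L_MIN_DEFAULT) -> float:
    """Shannon-Wiener length diversity of a 1-cm length-frequency distribution.

    ``counts`` maps length class (cm, lower bound) to count.  Classes below
    ``l_min`` are ignored; returns NaN when no fish reach ``l_min``.
    Natural log; 0*ln 0 := 0.
    """
    s = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    s = s[(s.index >= l_min) & (s > 0)]
    total = float(s.sum())
    if total == 0:
        return float("nan")
    p = s.to_numpy(dtype=float) / total
    return float(-np.sum(p * np.log(p)))


def l95(lengths=None, counts=None, l_min: float = L_MIN_DEFAULT) -> float:
    """95th percentile of the length distribution of fish >= ``l_min`` cm.

    Linear interpolation of order statistics (h = (n-1)*0.95 + 1).  Class
    counts are expanded at class lower bounds.  NaN when no fish qualify.
    """
    if (lengths is None) == (counts is None):
        raise ValueError("provide exactly one of lengths or counts")
    if counts is not None:
        s = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
        arr = np.repeat(s.index.to_numpy(dtype=float), s.to_numpy(dtype=int))
    else:
        arr = np.asarray(lengths, dtype=float)
    arr = arr[arr >= l_min]
    if arr.size == 0:
        return float("nan")
    return float(np.percentile(arr, 95))


def annual_ldi(catches: pd.DataFrame, sds=None, l_min: float = L_MIN_DEFAULT) -> pd.DataFrame:
    """Annual LDI pooling all hauls' class counts within each year."""
    df = catches
    if sds is not None:
        df = df[df["sd"].isin(set(int(s) for s in sds))]
    rows = []
    for year, grp in df.groupby("year"):
        counts = grp.groupby("length_class")["count"].sum()
        counts.index = counts.index.astype(float)
        val = ldi(counts, l_min)
        n = int(grp.loc[grp["length_class"] >= l_min, "count"].sum())
        rows.append((int(year), val, n, "ok" if np.isfinite(val) else "missing"))
    return pd.DataFrame(rows, columns=["year", "value", "n", "flag"]).set_index("year")


def annual_l95(catches: pd.DataFrame, sds=None, l_min: float = L_MIN_DEFAULT) -> pd.DataFrame:
    """Annual L95 from pooled haul class counts within each year."""
    df = catches
    if sds is not None:
        df = df[df["sd"].isin(set(int(s) for s in sds))]
    rows = []
    for year, grp in df.groupby("year"):
        counts = grp.groupby("length_class")["count"].sum()
        counts.index = counts.index.astype(float)
        val = l95(counts=counts, l_min=l_min)
        n = int(grp.loc[grp["length_class"] >= l_min, "count"].sum())
        rows.append((int(year), val, n, "ok" if np.isfinite(val) else "missing"))
    return pd.DataFrame(rows, columns=["year", "value", "n", "flag"]).set_index("year")


def catch_per_recruit(series: pd.DataFrame, lag: int = 4) -> pd.Series:
    """Catch-per-recruit: CPR_i = Catch_i / REC_{i-lag}, grams per recruit.

    Catch in tonnes (x 1e6 g), recruits in individuals.  Years whose lagged
    recruitment is unavailable or zero are missing.
    """
    if "catch" not in series.columns or "recruits" not in series.columns:
        raise ValueError("series table needs 'catch' and 'recruits' columns")
    catch = series["catch"]
    rec_lagged = series["recruits"].reindex(series.index - lag)
    rec_lagged.index = series.index
    with np.errstate(divide="ignore", invalid="ignore"):
        cpr = catch * 1e6 / rec_lagged
    cpr[rec_lagged == 0] = np.nan
    cpr.name = "cpr"
    return cpr


def total_mortality(f46, m46=None, year=None, m_default_before: int = 1991,
                    m_conventional: float = 0.2):
    """Total mortality Z46 = F46 + M46.

    When M46 is missing for a year before ``m_default_before``, the
    conventional value 0.2/yr is substituted; a missing M46 in a later year
    stays missing.  Accepts scalars or aligned pandas Series (year taken
    from the index when omitted).
    """
    if isinstance(f46, pd.Series):
        years = f46.index.to_numpy() if year is None else np.asarray(year)
        f = f46.to_numpy(dtype=float)
        m = (np.full_like(f, np.nan) if m46 is None
             else pd.Series(m46).reindex(f46.index).to_numpy(dtype=float))
        if np.any(f < 0) or np.any(m[np.isfinite(m)] < 0):
            raise ValueError("mortality rates must be non-negative")
        m = np.where(np.isnan(m) & (years < m_default_before), m_conventional, m)
        return pd.Series(f + m, index=f46.index, name="z46")
    f = float(f46)
    if f < 0:
        raise ValueError("F46 must be non-negative")
    if m46 is None or (isinstance(m46, float) and np.isnan(m46)):
        if year is not None and year < m_default_before:
            m = m_conventional
        else:
            return float("nan")
    else:
        m = float(m46)
        if m < 0:
            raise ValueError("M46 must be non-negative")
    return f + m


def exploitation_rate(f46, z46):
    """Exploitation rate ER = F46 / Z46 in [0, 1]; missing where Z46 = 0."""
    f = np.asarray(f46, dtype=float)
    z = np.asarray(z46, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        er = np.where(z > 0, f / z, np.nan)
    if isinstance(f46, pd.Series):
        return pd.Series(er, index=f46.index, name="er")
    return er if er.ndim else float(er)
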