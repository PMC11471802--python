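"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:

* ``grid_mle_ogive`` maximises the Bernoulli log-likelihood of the logistic
  maturity model by iteratively zoomed brute-force grid search over
  (alpha, beta) — no Newton steps, no linear algebra;
* ``kendall_s_oracle`` enumerates all ordered pairs explicitly;
* ``spearman_rho_oracle`` computes average ranks and the Pearson moment
  formula by hand.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from codtrends import GrowthParams, SimConfig, TruePopulation


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def _loglik(alpha: float, beta: float, length: np.ndarray, y: np.ndarray) -> float:
    eta = alpha + beta * length
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_mle_ogive(length, y, l50_range=(10.0, 90.0), beta_range=(0.001, 3.0)):
    """Brute-force grid maximisation of the logistic likelihood.

    Searches over (l50, beta) with alpha = -l50*beta — the likelihood
    surface is close to axis-aligned in this parameterisation, unlike the
    strongly correlated (alpha, beta) ridge — zooming the grid around the
    running optimum until the spacing is below 1e-6 (l50) and 1e-8 (beta).
    Returns (alpha, beta, l50)."""
    length = np.asarray(length, dtype=float)
    y = np.asarray(y, dtype=float)
    m_lo, m_hi = l50_range
    b_lo, b_hi = beta_range
    best = (0.0, 0.0)
    while True:
        mids = np.linspace(m_lo, m_hi, 81)
        betas = np.linspace(b_lo, b_hi, 61)
        ll = np.array([[_loglik(-m * b, b, length, y) for b in betas] for m in mids])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (mids[i], betas[j])
        dm = mids[1] - mids[0]
        db = betas[1] - betas[0]
        if dm < 1e-6 and db < 1e-8:
            break
        m_lo, m_hi = best[0] - 3 * dm, best[0] + 3 * dm
        b_lo, b_hi = best[1] - 3 * db, best[1] + 3 * db
    l50, beta = best
    return -l50 * beta, beta, l50


def kendall_s_oracle(x) -> int:
    """S = sum over ordered pairs of sign(x_j - x_i), by explicit enumeration."""
    x = list(x)
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    return s


def kendall_tau_b_oracle(x) -> float:
    """Tau-b with untied time: S / sqrt(n0 * (n0 - ties))."""
    x = list(x)
    n = len(x)
    n0 = n * (n - 1) / 2
    ties = 0
    for _, grp in itertools.groupby(sorted(x)):
        t = len(list(grp))
        ties += t * (t - 1) / 2
    if n0 - ties == 0:
        return 0.0
    return kendall_s_oracle(x) / math.sqrt(n0 * (n0 - ties))


def average_ranks(v):
    """Mid-ranks computed by hand (1-based, ties averaged)."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho_oracle(x, y) -> float:
    """Pearson moment correlation of the hand-computed average ranks."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_population() -> TruePopulation:
    return TruePopulation()


@pytest.fixture(scope="session")
def noiseless_population() -> TruePopulation:
    """Weights exactly on W = 0.01 * L^3 (no condition noise)."""
    return TruePopulation(condition_scale=0.0)


@pytest.fixture()
def sim_config() -> SimConfig:
    return SimConfig(seed=42, years=(1950, 1951, 1952), sample_size_per_year=400)


def simulate_maturity_sample(seed: int, n: int = 2000,
                             true_l50: float = 40.0, width: float = 8.0):
    """One year of coded maturity-at-length observations (lengths, mature)."""
    import codtrends as ct

    pop = TruePopulation(true_l50=true_l50, ogive_width=width)
    cfg = SimConfig(seed=seed, years=(1960,), sample_size_per_year=n)
    df = ct.simulate_individual_records(pop, cfg)
    coded = ct.code_maturity_column(df)
    sub = coded[coded["maturity_status"].isin(["immature", "mature"])]
    return (sub["length_cm"].to_numpy(),
            (sub["maturity_status"] == "mature").to_numpy())
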