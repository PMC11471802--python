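"""Synthetic survey-data generator with known ground truth.

Emulates the three historical record types a long-running demersal trawl
survey produces — individual-fish records (date, subdivision, length,
weight, sex, gonad maturity stage), haul-level length-frequency catch
records in 1-cm classes, and year-indexed stock-assessment series — from a
population with known von Bertalanffy growth, a known logistic
maturity-at-length ogive (true L50 and ogive width), exponential total
mortality and an allometric length--weight relationship.  Because the true
parameters are known, every downstream estimator (ogive fitting, condition
factors, size-structure indices, trend tests) has a parameter-recovery test
surface that needs no archival data.

Randomness uses numpy's PCG64 generator seeded through ``SeedSequence``;
each operation draws from its own deterministically derived child stream,
so outputs are reproducible across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "TruePopulation",
    "SimConfig",
    "vbgf_length",
    "maturity_probability",
    "simulate_individual_records",
    "simulate_catch_records",
    "simulate_ar1_series",
    "population_trajectory",
    "write_ground_truth",
]

# Fixed child-stream indices: stable names -> reproducible per-operation RNGs.
_STREAMS = {"individuals": 0, "catches": 1, "ar1": 2}

MAX_AGE = 15.0  # truncation age (years) for the exponential age structure
MIN_LENGTH = 1.0  # cm; floor for lengths after measurement noise


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Child PCG64 generator for a named operation under a single root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy growth parameters.

    l_inf : asymptotic length (cm), > 0
    k     : Brody growth coefficient (1/year), > 0
    t0    : age offset (year); a modelling artefact, may be negative

    The defaults are illustrative values for a large gadoid, not stock
    estimates for any real population.
    """

    l_inf: float = 110.0
    k: float = 0.15
    t0: float = -0.5

    def __post_init__(self) -> None:
        if not (self.l_inf > 0):
            raise ValueError(f"l_inf must be > 0, got {self.l_inf}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class TruePopulation:
    """Ground-truth population used by the simulator.

    true_l50        : length at 50% maturity (cm)
    ogive_width     : length span between 25% and 75% maturity (cm); the
                      implied logistic slope is beta = 2*ln(3)/ogive_width
    z_total         : instantaneous total mortality (1/year)
    recruits_per_year : nominal recruitment (individuals), echoed in the
                      ground-truth sidecar
    lw_a, lw_b      : allometric length--weight coefficients, W = a*L^b
                      (W in g, L in cm); lw_b is near 3 for isometric growth
    condition_scale : sigma of multiplicative lognormal weight noise
    length_obs_sd   : Gaussian length-measurement noise (cm)
    """

    growth: GrowthParams = field(default_factory=GrowthParams)
    true_l50: float = 40.0
    ogive_width: float = 8.0
    z_total: float = 0.5
    recruits_per_year: float = 5e8
    lw_a: float = 0.01
    lw_b: float = 3.0
    condition_scale: float = 0.1
    length_obs_sd: float = 0.5

    def __post_init__(self) -> None:
        if not (self.true_l50 > 0):
            raise ValueError("true_l50 must be > 0")
        if not (self.ogive_width > 0):
            raise ValueError("ogive_width must be > 0")
        if self.z_total < 0:
            raise ValueError("z_total must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Sampling design for a simulated survey."""

    seed: int
    years: tuple[int, ...]
    subdivisions: tuple[int, ...] = (25, 26, 27, 28, 29)
    sample_size_per_year: int = 500
    months: tuple[int, ...] = (4, 5, 6, 7, 8)
    range_fraction: float = 0.1  # fraction of maturity stages written as ranges "a-b"

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "subdivisions", tuple(int(s) for s in self.subdivisions))
        object.__setattr__(self, "months", tuple(int(m) for m in self.months))


def vbgf_length(age, growth: GrowthParams):
    """Expected length at age under von Bertalanffy growth.

    L(t) = L_inf * (1 - exp(-K * (t - t0))).  Monotone non-decreasing in age
    for age >= t0; negative values for age < t0 are returned as-is (the
    caller clamps).
    """
    age = np.asarray(age, dtype=float)
    out = growth.l_inf * (1.0 - np.exp(-growth.k * (age - growth.t0)))
    return out if out.ndim else float(out)


def maturity_probability(length, true_l50: float, ogive_width: float):
    """Probability of being mature at length, logistic in length.

    Equals 0.5 at ``true_l50``; the width is the length span between the 25%
    and 75% points, so the slope is beta = 2*ln(3)/ogive_width.
    """
    if not (ogive_width > 0):
        raise ValueError("ogive_width must be > 0")
    beta = 2.0 * np.log(3.0) / ogive_width
    length = np.asarray(length, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-beta * (length - true_l50)))
    return out if out.ndim else float(out)


def population_trajectory(
    start: TruePopulation,
    years: Sequence[int],
    true_l50_end: float | None = None,
    l_inf_end: float | None = None,
) -> dict[int, TruePopulation]:
    """Linear per-year interpolation of true L50 (and optionally L_inf).

    Returns a year -> TruePopulation mapping usable wherever a single
    population is accepted; used to emulate a secular decline in size at
    maturation and growth potential.
    """
    years = [int(y) for y in years]
    n = len(years)
    out: dict[int, TruePopulation] = {}
    for i, y in enumerate(years):
        frac = i / (n - 1) if n > 1 else 0.0
        l50 = start.true_l50 + frac * ((true_l50_end - start.true_l50) if true_l50_end is not None else 0.0)
        growth = start.growth
        if l_inf_end is not None:
            growth = GrowthParams(
                l_inf=start.growth.l_inf + frac * (l_inf_end - start.growth.l_inf),
                k=start.growth.k,
                t0=start.growth.t0,
            )
        out[y] = TruePopulation(
            growth=growth,
            true_l50=l50,
            ogive_width=start.ogive_width,
            z_total=start.z_total,
            recruits_per_year=start.recruits_per_year,
            lw_a=start.lw_a,
            lw_b=start.lw_b,
            condition_scale=start.condition_scale,
            length_obs_sd=start.length_obs_sd,
        )
    return out


def _pop_for_year(pop, year: int) -> TruePopulation:
    if isinstance(pop, Mapping):
        return pop[year]
    return pop


def _draw_ages(rng: np.random.Generator, n: int, z: float) -> np.ndarray:
    """Ages from an exponential(z) survival curve truncated at MAX_AGE."""
    u = rng.random(n)
    if z <= 0:
        return u * MAX_AGE
    # inverse CDF of the truncated exponential
    return -np.log1p(-u * (1.0 - np.exp(-z * MAX_AGE))) / z


def _draw_lengths(rng: np.random.Generator, pop: TruePopulation, n: int) -> np.ndarray:
    ages = _draw_ages(rng, n, pop.z_total)
    lengths = vbgf_length(ages, pop.growth) + rng.normal(0.0, pop.length_obs_sd, n)
    return np.maximum(lengths, MIN_LENGTH)


def simulate_individual_records(pop, cfg: SimConfig) -> pd.DataFrame:
    """Individual-fish records: date, sd, gear, length_cm, weight_g, sex, maturity.

    ``pop`` is a TruePopulation or a year -> TruePopulation mapping.  Ages
    come from exponential survival at ``z_total`` truncated at 15 years,
    lengths from the growth curve plus Gaussian measurement noise, weights
    from W = a*L^b times lognormal noise, and maturity from a Bernoulli draw
    on the logistic ogive evaluated at the *recorded* length.  Mature fish
    get a uniform Maier stage from {3..7}, immature from {1, 2}; a
    ``range_fraction`` of stages are rendered as ranges like ``"2-3"`` to
    exercise downstream range coding.  Deterministic for a fixed seed.
    """
    if len(cfg.years) == 0:
        warnings.warn("empty year range: no individual records simulated", stacklevel=2)
        return pd.DataFrame(
            columns=["date", "sd", "gear", "length_cm", "weight_g", "sex", "maturity"]
        )
    rng = _rng(cfg.seed, "individuals")
    frames = []
    for year in cfg.years:
        p = _pop_for_year(pop, year)
        n = cfg.sample_size_per_year
        # lengths recorded at 0.1 cm resolution; weights derive from the
        # recorded length so W = a*L^b holds exactly when condition_scale = 0
        lengths = np.round(_draw_lengths(rng, p, n), 1)
        weights = p.lw_a * lengths**p.lw_b
        if p.condition_scale > 0:
            weights = weights * np.exp(rng.normal(0.0, p.condition_scale, n))
        mature = rng.random(n) < maturity_probability(lengths, p.true_l50, p.ogive_width)
        stages = np.where(mature, rng.integers(3, 8, n), rng.integers(1, 3, n))
        as_range = rng.random(n) < cfg.range_fraction
        maturity = np.where(
            as_range,
            [f"{s}-{min(s + 1, 8)}" for s in stages],
            stages.astype(str),
        )
        months = rng.choice(cfg.months, n)
        days = rng.integers(1, 29, n)
        sds = rng.choice(cfg.subdivisions, n)
        sex = rng.choice(["female", "male"], n)
        frames.append(
            pd.DataFrame(
                {
                    "date": [f"{year:04d}-{m:02d}-{d:02d}" for m, d in zip(months, days)],
                    "sd": sds,
                    "gear": "trawl",
                    "length_cm": lengths,
                    "weight_g": weights,
                    "sex": sex,
                    "maturity": maturity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_catch_records(pop, cfg: SimConfig) -> pd.DataFrame:
    """Haul-level length-frequency records in long form.

    One haul per (year, subdivision); counts per 1-cm length class are the
    floor-binned simulated lengths (class value = lower bound), so the sum
    of class counts equals the number of simulated fish in the haul.
    """
    if len(cfg.years) == 0:
        warnings.warn("empty year range: no catch records simulated", stacklevel=2)
        return pd.DataFrame(columns=["haul", "date", "sd", "length_class", "count"])
    rng = _rng(cfg.seed, "catches")
    n_sd = len(cfg.subdivisions)
    per_haul = max(cfg.sample_size_per_year // n_sd, 1)
    rows = []
    for year in cfg.years:
        p = _pop_for_year(pop, year)
        for sd in cfg.subdivisions:
            lengths = _draw_lengths(rng, p, per_haul)
            classes = np.floor(lengths).astype(int)
            month = int(rng.choice(cfg.months))
            day = int(rng.integers(1, 29))
            haul = f"H{year:04d}-{sd:02d}"
            date = f"{year:04d}-{month:02d}-{day:02d}"
            uniq, counts = np.unique(classes, return_counts=True)
            for lc, c in zip(uniq, counts):
                rows.append((haul, date, sd, int(lc), int(c)))
    return pd.DataFrame(rows, columns=["haul", "date", "sd", "length_class", "count"])


def simulate_ar1_series(
    n: int,
    phi: float,
    trend: float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
    start_year: int = 0,
) -> pd.Series:
    """AR(1) noise around a linear trend: x_t = trend*t + e_t.

    e_t = phi*e_{t-1} + N(0, sd^2), with stationary initialization
    e_0 ~ N(0, sd^2/(1-phi^2)).  Used as the calibration input for the
    block-bootstrap trend test and to emulate autocorrelated assessment and
    forage series.  |phi| must be < 1.
    """
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS["ar1"]]))
    e = np.empty(n)
    if sd == 0:
        e[:] = 0.0
    else:
        e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        innov = rng.normal(0.0, sd, n - 1)
        for t in range(1, n):
            e[t] = phi * e[t - 1] + innov[t - 1]
    t = np.arange(n)
    return pd.Series(trend * t + e, index=start_year + t, name="x")


def write_ground_truth(path, pop, cfg: SimConfig) -> None:
    """JSON sidecar with the true parameters and seed, for test harnesses."""
    if isinstance(pop, Mapping):
        pop_json = {str(y): asdict(p) for y, p in pop.items()}
    else:
        pop_json = asdict(pop)
    payload = {"population": pop_json, "config": asdict(cfg)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
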