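"""Co-culture growth-competition assays linking futile-cycle cost to fitness.

Two differentially labelled strains grow together under a serial-dilution
regime (default: diluted 1:50 twice a day, keeping cultures in exponential
phase).  A selection coefficient ``s`` penalises the competitor strain's
growth rate only in the stimulated culture; a paired unstimulated culture
normalises away marker-specific offsets.  Strain ratios are measured daily
by flow cytometry, modelled as a multinomial draw of ``n`` cells; the
divergence rate of the normalized ratio is the OLS slope of its log versus
time, and divided by the growth rate it recovers ``s`` (d/dt ln(N1/N2) =
r - r(1-s) = r*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress, t as t_dist

__all__ = [
    "CocultureConfig",
    "CocultureTrajectory",
    "simulate_coculture",
    "divergence_rate",
    "fitness_defect",
    "growth_rate_from_doubling",
    "predicted_fitness_cost",
]

MINUTES_PER_DAY = 1440.0


@dataclass
class CocultureConfig:
    """Competition-assay settings.

    ``s`` is the fitness defect of the competitor (strain 2) realised only in
    the stimulated culture; the reference strain grows at rate ``r`` per day.
    """

    r: float = 10.0                      # reference growth rate, 1/day
    s: float = 0.005                     # selection coefficient (0 <= s < 1)
    days: int = 7
    dilution_factor: float = 50.0        # 1:50 into fresh medium
    dilutions_per_day: int = 2
    carrying_capacity: Optional[float] = None   # cells/ml; None = never saturates
    n0_reference: float = 1e6
    n0_competitor: float = 1e6
    count_per_sample: Optional[int] = 10_000    # flow events; None = exact ratios
    marker_cost: float = 0.0                    # marker-specific growth cost, both cultures
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.s < 1):
            raise ValueError("selection coefficient must satisfy 0 <= s < 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must be > 1")
        if self.r <= 0 or self.days < 1:
            raise ValueError("invalid growth rate or duration")
        if min(self.n0_reference, self.n0_competitor) <= 0:
            raise ValueError("initial counts must be > 0")


@dataclass
class CocultureTrajectory:
    """Daily measured strain ratios for a stimulated/unstimulated pair."""

    days: np.ndarray
    ratio_stimulated: np.ndarray     # reference/competitor (Ng/Tq-style) ratio
    ratio_unstimulated: np.ndarray
    config: CocultureConfig
    extinct: bool = False

    @property
    def normalized_ratio(self) -> np.ndarray:
        return self.ratio_stimulated / self.ratio_unstimulated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days,
            "ratio_plus_pheromone": self.ratio_stimulated,
            "ratio_minus_pheromone": self.ratio_unstimulated,
            "normalized_ratio": self.normalized_ratio,
        })


def _grow(n1: float, n2: float, r1: float, r2: float, dt_days: float,
          capacity: Optional[float]) -> Tuple[float, float]:
    """Exponential growth for dt; with a carrying capacity, growth stops for
    both strains once the combined culture reaches it."""
    if capacity is not None and n1 + n2 >= capacity:
        return n1, n2
    if capacity is not None:
        total_end = n1 * np.exp(r1 * dt_days) + n2 * np.exp(r2 * dt_days)
        if total_end > capacity:
            tau = brentq(
                lambda t: n1 * np.exp(r1 * t) + n2 * np.exp(r2 * t) - capacity,
                0.0, dt_days)
            dt_days = tau
    return n1 * np.exp(r1 * dt_days), n2 * np.exp(r2 * dt_days)


def simulate_coculture(config: CocultureConfig) -> CocultureTrajectory:
    """Simulate the paired (+/- stimulus) co-cultures and daily measurements.

    Growth between dilution events is exponential: rate ``r`` for the
    reference strain everywhere, ``r(1-s)`` for the competitor in the
    stimulated culture only.  Dilution divides both strains equally and so
    never changes the true ratio.  Daily flow measurements draw
    ``count_per_sample`` cells multinomially from each culture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.dilutions_per_day
    marker = config.r * config.marker_cost  # additive rate penalty on the competitor
    cultures = {
        "plus": [config.n0_reference, config.n0_competitor,
                 config.r, config.r * (1 - config.s) - marker],
        "minus": [config.n0_reference, config.n0_competitor,
                  config.r, config.r - marker],
    }
    ratios = {"plus": [], "minus": []}
    extinct = False

    def measure(n1, n2):
        nonlocal extinct
        if min(n1, n2) <= 0:
            extinct = True
            return np.nan
        if config.count_per_sample is None:
            return n1 / n2
        p = n1 / (n1 + n2)
        c1 = rng.binomial(config.count_per_sample, p)
        c2 = config.count_per_sample - c1
        if c2 == 0:
            extinct = True
            return np.nan
        return c1 / c2

    for name in ("plus", "minus"):
        ratios[name].append(measure(cultures[name][0], cultures[name][1]))
    for _ in range(config.days):
        for _ in range(config.dilutions_per_day):
            for name, st in cultures.items():
                n1, n2 = _grow(st[0], st[1], st[2], st[3], dt, config.carrying_capacity)
                st[0], st[1] = n1 / config.dilution_factor, n2 / config.dilution_factor
        for name in ("plus", "minus"):
            ratios[name].append(measure(cultures[name][0], cultures[name][1]))

    return CocultureTrajectory(
        days=np.arange(config.days + 1, dtype=float),
        ratio_stimulated=np.asarray(ratios["plus"]),
        ratio_unstimulated=np.asarray(ratios["minus"]),
        config=config,
        extinct=extinct,
    )


@dataclass
class DivergenceFit:
    slope: float            # 1/day
    intercept: float
    ci95: Tuple[float, float]
    stderr: float


def divergence_rate(trajectory_or_frame, confidence: float = 0.95) -> DivergenceFit:
    """OLS slope of log(normalized ratio) versus time, with a t-based CI."""
    if isinstance(trajectory_or_frame, CocultureTrajectory):
        days = trajectory_or_frame.days
        ratio = trajectory_or_frame.normalized_ratio
    else:
        df = trajectory_or_frame
        days = np.asarray(df["day"], dtype=float)
        ratio = np.asarray(df["normalized_ratio"], dtype=float)
    ok = np.isfinite(ratio)
    days, ratio = days[ok], ratio[ok]
    if len(days) < 3:
        raise ValueError("need >= 3 time points for a divergence fit")
    if np.any(ratio <= 0):
        raise ValueError("non-positive ratios cannot be log-fitted")
    res = linregress(days, np.log(ratio))
    dof = len(days) - 2
    half = t_dist.ppf(0.5 + confidence / 2, dof) * res.stderr if dof > 0 else np.inf
    return DivergenceFit(slope=float(res.slope), intercept=float(res.intercept),
                         ci95=(float(res.slope - half), float(res.slope + half)),
                         stderr=float(res.stderr))


def fitness_defect(slope: float, growth_rate: float) -> float:
    """Convert a divergence slope (1/day) into a percent fitness defect,
    100 * slope / growth_rate."""
    if growth_rate <= 0:
        raise ValueError("growth rate must be > 0")
    return 100.0 * slope / growth_rate


def growth_rate_from_doubling(doubling_time_min: float) -> float:
    """Exponential growth rate (1/day) from a doubling time in minutes."""
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be > 0")
    return float(np.log(2.0) / doubling_time_min * MINUTES_PER_DAY)


def predicted_fitness_cost(atp_rate_per_cell: float, total_energy_budget: float) -> float:
    """Signalling energy flux as a percent of the total cellular budget.

    Under the energy-proportional-fitness assumption this percentage is the
    expected selection coefficient of running the futile cycle.
    """
    if total_energy_budget <= 0:
        raise ValueError("energy budget must be > 0")
    if atp_rate_per_cell < 0:
        raise ValueError("ATP rate must be >= 0")
    return 100.0 * atp_rate_per_cell / total_energy_budget
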