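"""Uncertainty apparatus: Monte Carlo over mortality, exact Poisson intervals,
and the scaling / two-way sensitivity grids.

The probability of death after an unwitnessed overdose (Pn) is the dominant
unknown; it is propagated three ways: (1) a Monte Carlo simulation drawing Pn
from a configurable distribution (uniform over the 8-80% literature range by
default); (2) an exact (Garwood) Poisson confidence interval for the
on-service death probability Pi, whose observed count is zero; (3)
deterministic grids — deaths averted across service scale N and Pi, and net
benefit / benefit-to-cost ratio across operating-budget multipliers and Pn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import chi2

from .benefits import benefit_cost_ratio, net_benefit, value_of_deaths_averted
from .currency import D

__all__ = [
    "MonteCarloSpec", "MonteCarloSummary", "SensitivityGrid",
    "poisson_exact_ci", "deaths_averted_grid", "two_way_sensitivity",
    "monte_carlo_mortality", "break_even_mortality",
]


@dataclass(frozen=True)
class MonteCarloSpec:
    """Sampling distribution for Pn.

    ``distribution`` is ``"uniform"`` or ``"triangular"`` over
    ``(low, high[, mode])``, or ``"fixed"`` at ``low``.
    """

    distribution: str = "uniform"
    low: float = 0.08
    high: float = 0.80
    mode: float | None = None
    n_draws: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.distribution not in {"uniform", "triangular", "fixed"}:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "fixed":
            object.__setattr__(self, "high", self.low)
        if not 0 <= self.low <= self.high <= 1:
            raise ValueError("require 0 <= low <= high <= 1")
        if self.distribution == "triangular":
            mode = self.mode if self.mode is not None else (self.low + self.high) / 2
            if not self.low <= mode <= self.high:
                raise ValueError("mode must lie within [low, high]")
            object.__setattr__(self, "mode", mode)
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class MonteCarloSummary:
    """Percentile summary of the Pn draws and the implied deaths averted."""

    spec: MonteCarloSpec
    n: int
    mean_pn: float
    pn_interval: tuple[float, float]
    mean_deaths_averted: float
    deaths_averted_interval: tuple[float, float]
    mean_value: Decimal

    def to_dict(self) -> dict:
        return {
            "distribution": self.spec.distribution,
            "low": self.spec.low, "high": self.spec.high,
            "mode": self.spec.mode, "n_draws": self.spec.n_draws,
            "seed": self.spec.seed, "n": self.n,
            "mean_pn": self.mean_pn, "pn_interval": list(self.pn_interval),
            "mean_deaths_averted": self.mean_deaths_averted,
            "deaths_averted_interval": list(self.deaths_averted_interval),
            "mean_value": str(self.mean_value),
        }


@dataclass(frozen=True)
class SensitivityGrid:
    """Rectangular grid of results over two strictly ordered axes."""

    row_axis: tuple
    col_axis: tuple
    cells: tuple              # cells[i][j] for row_axis[i], col_axis[j]
    row_label: str = "rows"
    col_label: str = "cols"

    def __post_init__(self):
        rows = tuple(self.row_axis)
        cols = tuple(self.col_axis)
        for axis, name in ((rows, "row_axis"), (cols, "col_axis")):
            if any(a >= b for a, b in zip(axis, axis[1:])) and \
               any(a <= b for a, b in zip(axis, axis[1:])):
                raise ValueError(f"{name} must be strictly ordered")
        cells = tuple(tuple(row) for row in self.cells)
        if len(cells) != len(rows) or any(len(r) != len(cols) for r in cells):
            raise ValueError("cell matrix shape must be rows x columns")
        object.__setattr__(self, "row_axis", rows)
        object.__setattr__(self, "col_axis", cols)
        object.__setattr__(self, "cells", cells)

    def cell(self, row_value, col_value):
        return self.cells[self.row_axis.index(row_value)][self.col_axis.index(col_value)]


def poisson_exact_ci(observed_deaths: int, n_exposed: int,
                     level: float = 0.95) -> tuple[float, float]:
    """Garwood exact confidence interval for a per-exposure death probability.

    Treats the death count as Poisson and inverts its tails with chi-square
    quantiles; bounds are divided by the number exposed.  The lower bound is
    0 when no deaths were observed.
    """
    if n_exposed <= 0:
        raise ValueError("n_exposed must be > 0")
    if observed_deaths < 0:
        raise ValueError("observed_deaths must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1 - level
    k = observed_deaths
    low = 0.0 if k == 0 else chi2.ppf(alpha / 2, 2 * k) / 2 / n_exposed
    high = chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2 / n_exposed
    return low, high


def deaths_averted_grid(populations, pi_values, pn) -> SensitivityGrid:
    """Deaths averted round(N x (Pn - Pi)) across service scale and Pi."""
    pn = D(pn)
    pis = [D(p) for p in pi_values]
    if any(not 0 <= p <= 1 for p in [pn, *pis]):
        raise ValueError("probabilities must lie in [0, 1]")
    cells = [
        [int((D(n) * (pn - pi)).quantize(Decimal(1), rounding=ROUND_HALF_UP))
         for pi in pis]
        for n in populations
    ]
    return SensitivityGrid(tuple(populations), tuple(pis), cells,
                           row_label="n_service_users",
                           col_label="p_death_on_service")


def two_way_sensitivity(n: int, vol, operating, medical,
                        cost_multipliers, pn_values) -> SensitivityGrid:
    """Net benefit and benefit-to-cost ratio across operating-budget
    multipliers (rows) and unwitnessed-overdose mortality Pn (columns).

    Only the operating budget is scaled; medical costs are held fixed.  Each
    cell is ``(net_benefit, ratio)`` with the ratio rounded to 2 decimals.
    """
    operating, medical = D(operating), D(medical)
    mults = [D(m) for m in cost_multipliers]
    if any(m <= 0 for m in mults):
        raise ValueError("cost multipliers must be > 0")
    pns = [D(p) for p in pn_values]
    cells = []
    for m in mults:
        row = []
        for pn in pns:
            value = value_of_deaths_averted(n, pn, vol)
            nb = net_benefit(value, m * operating, medical)
            ratio = benefit_cost_ratio(value, m * operating, medical)
            row.append((nb, ratio.quantize(D("0.01"), rounding=ROUND_HALF_UP)))
        cells.append(row)
    return SensitivityGrid(tuple(mults), tuple(pns), cells,
                           row_label="operating_cost_multiplier",
                           col_label="p_death_unwitnessed")


def monte_carlo_mortality(spec: MonteCarloSpec, n: int,
                          vol) -> MonteCarloSummary:
    """Propagate Pn uncertainty to deaths averted by simulation.

    Draws Pn per ``spec`` (deterministic given its seed) and summarises the
    draws and the implied deaths averted N x Pn by their mean and central
    95% (2.5/97.5 percentile) interval.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "fixed":
        draws = np.full(spec.n_draws, spec.low)
    elif spec.distribution == "uniform":
        draws = rng.uniform(spec.low, spec.high, spec.n_draws)
    else:
        draws = rng.triangular(spec.low, spec.mode, spec.high, spec.n_draws)
    deaths = n * draws
    lo, hi = np.percentile(draws, [2.5, 97.5])
    dlo, dhi = np.percentile(deaths, [2.5, 97.5])
    mean_pn = float(draws.mean())
    return MonteCarloSummary(
        spec=spec, n=n,
        mean_pn=mean_pn,
        pn_interval=(float(lo), float(hi)),
        mean_deaths_averted=float(deaths.mean()),
        deaths_averted_interval=(float(dlo), float(dhi)),
        mean_value=value_of_deaths_averted(n, D(repr(mean_pn)), vol),
    )


def break_even_mortality(total_cost, n: int, vol) -> Decimal:
    """The Pn at which the value of deaths averted equals total program cost."""
    total_cost, vol = D(total_cost), D(vol)
    denom = D(n) * vol
    if denom <= 0:
        raise ValueError("n x value of one life must be > 0")
    if total_cost < 0:
        raise ValueError("total_cost must be >= 0")
    return total_cost / denom
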