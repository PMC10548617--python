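"""Human-capital valuation of prevented deaths and net-benefit accounting.

The value of one life lost to overdose follows the human-capital approach:
average annual income x employment rate x remaining productive years
(retirement age minus median age at death).  Deaths averted among N unique
overdosing service users follow the counterfactual Np = N(Pn - Pi), where Pn
is the probability of death after an unwitnessed overdose and Pi the
probability of death while using the service (zero in the base case: no
deaths have occurred on the line).  Net benefit is the value of deaths
averted minus operating and medical costs; the benefit-to-cost ratio shares
that denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal

from .currency import D, cents
from .parameters import LifeValueParameters, ParameterError

__all__ = [
    "MortalityAssumption", "CbaResult",
    "productive_years", "value_of_one_life", "deaths_averted",
    "value_of_deaths_averted", "net_benefit", "benefit_cost_ratio",
    "life_years_and_cost_per_life_year",
]


@dataclass(frozen=True)
class MortalityAssumption:
    """Counterfactual mortality probabilities.

    ``p_unwitnessed`` (Pn) is the probability of death after an unwitnessed
    overdose; ``p_on_service`` (Pi) the probability of death despite using
    the service.  ``pn_range`` brackets Pn for reporting ranges (the
    literature span 8-80% by default).
    """

    p_unwitnessed: Decimal = D("0.45")
    p_on_service: Decimal = D("0")
    pn_range: tuple[Decimal, Decimal] = (D("0.08"), D("0.80"))

    def __post_init__(self):
        pn = D(self.p_unwitnessed)
        pi = D(self.p_on_service)
        for name, p in (("p_unwitnessed", pn), ("p_on_service", pi)):
            if not 0 <= p <= 1:
                raise ParameterError(f"{name}: must be in [0, 1], got {p}")
        low, high = D(self.pn_range[0]), D(self.pn_range[1])
        if not 0 <= low <= high <= 1:
            raise ParameterError(f"pn_range: must be ordered within [0, 1]")
        object.__setattr__(self, "p_unwitnessed", pn)
        object.__setattr__(self, "p_on_service", pi)
        object.__setattr__(self, "pn_range", (low, high))
        if pi > pn:
            warnings.warn(
                "p_on_service exceeds p_unwitnessed: the service is harmful "
                "under this assumption and deaths averted will be negative",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CbaResult:
    """One period's (or the total's) cost-benefit outcome."""

    period: str
    n_unique_overdoses: int
    deaths_averted: Decimal
    value_of_life: Decimal
    value_of_deaths_averted: Decimal
    value_range: tuple[Decimal, Decimal]
    operating_cost: Decimal
    medical_cost: Decimal
    net_benefit: Decimal
    net_benefit_range: tuple[Decimal, Decimal]
    bc_ratio: Decimal
    bc_ratio_range: tuple[Decimal, Decimal]
    life_years_saved: Decimal
    cost_per_life_year: Decimal

    @property
    def total_cost(self) -> Decimal:
        return self.operating_cost + self.medical_cost


def productive_years(lv: LifeValueParameters) -> Decimal:
    """Productive years of life lost per death (retirement - age at death)."""
    years = lv.retirement_age - lv.median_age_at_death
    if years <= 0:
        raise ParameterError("retirement_age: must exceed median_age_at_death")
    return years


def value_of_one_life(lv: LifeValueParameters) -> Decimal:
    """Human-capital value of one life: income x employment x productive years."""
    return cents(lv.annual_income * lv.employment_rate * productive_years(lv))


def deaths_averted(n: int, m: MortalityAssumption) -> Decimal:
    """Expected deaths averted Np = N(Pn - Pi), unrounded."""
    if n < 0:
        raise ParameterError("n: must be >= 0")
    return D(n) * (m.p_unwitnessed - m.p_on_service)


def value_of_deaths_averted(n: int, pn, vol) -> Decimal:
    """Value of deaths averted at Pi = 0: N x Pn x value of one life."""
    if n < 0:
        raise ParameterError("n: must be >= 0")
    return cents(D(n) * D(pn) * D(vol))


def net_benefit(value, operating, medical) -> Decimal:
    """Net benefit: value of deaths averted minus operating and medical costs."""
    return cents(D(value) - D(operating) - D(medical))


def benefit_cost_ratio(value, operating, medical) -> Decimal:
    """Benefit per dollar spent: value / (operating + medical). Unrounded."""
    total = D(operating) + D(medical)
    if total <= 0:
        raise ZeroDivisionError("benefit-cost ratio undefined for zero total cost")
    return D(value) / total


def life_years_and_cost_per_life_year(deaths_prevented, vol,
                                      py) -> tuple[Decimal, Decimal]:
    """Life-years saved and cost per life-year for a prevented-death count.

    ``cost_per_life_year`` reduces to ``vol / py`` and is therefore the same
    for every positive death count.
    """
    deaths_prevented, py = D(deaths_prevented), D(py)
    if deaths_prevented < 0:
        raise ParameterError("deaths_prevented: must be >= 0")
    if py <= 0:
        raise ParameterError("productive_years: must be > 0")
    life_years = deaths_prevented * py
    if life_years == 0:
        raise ZeroDivisionError("cost per life-year undefined for zero life-years")
    return life_years, cents(D(vol) / py)
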