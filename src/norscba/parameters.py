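"""Economic parameter registry.

Typed containers for every unit cost, probability and value-of-life input the
cost-benefit model consumes, with currency-year bookkeeping, YAML/JSON
(de)serialisation and a bundled ``"nors2022"`` profile holding the published
2022-CAD reference costs for the National Overdose Response Service (NORS):
EMS call-out $518 (range 240-848), emergency-department visit $1,061,
physician assessment $176 inflated to $196.83, nasal naloxone $125,
hospitalization $7,803 (range 6,620-13,647) at probability 0.33, and funded
operating budgets of $787,500.00 and $580,875.00 for the two funding periods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal
from pathlib import Path
from typing import Mapping

import yaml

from .currency import D, cents

__all__ = [
    "ParameterError",
    "CostParameters",
    "LifeValueParameters",
    "adjust_for_inflation",
    "load_parameters",
    "save_parameters",
    "nors2022",
]


class ParameterError(ValueError):
    """A parameter failed validation; the message names the offending field."""


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ParameterError(f"{field_name}: {message}")


def _nonneg(value, field_name: str) -> Decimal:
    value = D(value)
    _require(value >= 0, field_name, f"must be >= 0, got {value}")
    return value


def _prob(value, field_name: str) -> Decimal:
    value = D(value)
    _require(0 <= value <= 1, field_name, f"must be in [0, 1], got {value}")
    return value


def _range_pair(pair, point: Decimal, field_name: str) -> tuple[Decimal, Decimal]:
    low, high = (D(pair[0]), D(pair[1]))
    _require(low <= high, field_name, f"range must be ordered, got ({low}, {high})")
    _require(low <= point <= high, field_name,
             f"range ({low}, {high}) must contain the point value {point}")
    return low, high


@dataclass(frozen=True)
class CostParameters:
    """Unit costs and probabilities of the medical-systems cost model.

    All amounts are in ``currency_year`` CAD.  ``physician_fee_base`` is the
    source-year fee; the model always consumes the inflation-adjusted
    ``physician_fee``.  ``community_response_cost`` defaults to the price of
    one nasal naloxone kit, the only supply consumed by a community response.
    """

    ems_fee: Decimal = D("518.00")
    ems_fee_range: tuple[Decimal, Decimal] = (D("240"), D("848"))
    ed_visit_cost: Decimal = D("1061.00")
    physician_fee_base: Decimal = D("176.00")
    physician_fee: Decimal = D("196.83")
    naloxone_cost: Decimal = D("125.00")
    hospitalization_cost: Decimal = D("7803.00")
    hospitalization_cost_range: tuple[Decimal, Decimal] = (D("6620"), D("13647"))
    hospitalization_prob: Decimal = D("0.33")
    community_response_cost: Decimal | None = None
    operating_cost_by_period: Mapping[str, Decimal] = field(
        default_factory=lambda: {
            "Funded 1": D("787500.00"),
            "Funded 2": D("580875.00"),
        }
    )
    reported_total_operating_cost: Decimal | None = None
    currency_year: int = 2022

    def __post_init__(self):
        for name in ("ems_fee", "ed_visit_cost", "physician_fee_base",
                     "physician_fee", "naloxone_cost", "hospitalization_cost"):
            object.__setattr__(self, name, _nonneg(getattr(self, name), name))
        object.__setattr__(self, "hospitalization_prob",
                           _prob(self.hospitalization_prob, "hospitalization_prob"))
        if self.community_response_cost is None:
            object.__setattr__(self, "community_response_cost", self.naloxone_cost)
        else:
            object.__setattr__(self, "community_response_cost",
                               _nonneg(self.community_response_cost,
                                       "community_response_cost"))
        object.__setattr__(self, "ems_fee_range",
                           _range_pair(self.ems_fee_range, self.ems_fee, "ems_fee_range"))
        object.__setattr__(self, "hospitalization_cost_range",
                           _range_pair(self.hospitalization_cost_range,
                                       self.hospitalization_cost,
                                       "hospitalization_cost_range"))
        oc = {str(k): _nonneg(v, f"operating_cost_by_period[{k!r}]")
              for k, v in dict(self.operating_cost_by_period).items()}
        object.__setattr__(self, "operating_cost_by_period", oc)
        if self.reported_total_operating_cost is not None:
            object.__setattr__(self, "reported_total_operating_cost",
                               _nonneg(self.reported_total_operating_cost,
                                       "reported_total_operating_cost"))

    @property
    def total_operating_cost(self) -> Decimal:
        """Sum of the per-period operating budgets."""
        return sum(self.operating_cost_by_period.values(), D(0))


@dataclass(frozen=True)
class LifeValueParameters:
    """Inputs to the human-capital value of one life lost to overdose.

    ``annual_income`` is the average income of the age group containing the
    median age at death; ``employment_rate`` the assumed share gainfully
    employed; the difference ``retirement_age - median_age_at_death`` is the
    productive years of life lost per death.
    """

    annual_income: Decimal = D("73530")
    employment_rate: Decimal = D("0.67")
    median_age_at_death: Decimal = D("38")
    retirement_age: Decimal = D("64.8")

    def __post_init__(self):
        object.__setattr__(self, "annual_income",
                           _nonneg(self.annual_income, "annual_income"))
        object.__setattr__(self, "employment_rate",
                           _prob(self.employment_rate, "employment_rate"))
        object.__setattr__(self, "median_age_at_death", D(self.median_age_at_death))
        object.__setattr__(self, "retirement_age", D(self.retirement_age))
        _require(self.retirement_age > self.median_age_at_death, "retirement_age",
                 "must exceed median_age_at_death")


def adjust_for_inflation(amount, factor) -> Decimal:
    """Scale an amount by an inflation factor, rounding half-up to cents.

    The factor is a plain ratio of price levels; no CPI lookup is performed.
    """
    amount = _nonneg(amount, "amount")
    factor = D(factor)
    if factor <= 0:
        raise ParameterError(f"factor: must be > 0, got {factor}")
    return cents(amount * factor)


def nors2022() -> tuple[CostParameters, LifeValueParameters]:
    """The bundled 2022 NORS parameter profile (all published reference values)."""
    return (
        CostParameters(reported_total_operating_cost=D("1366749.00")),
        LifeValueParameters(),
    )


_PROFILES = {"nors2022": nors2022}

_COST_FIELDS = {
    "ems_fee", "ems_fee_range", "ed_visit_cost", "physician_fee_base",
    "physician_fee", "naloxone_cost", "hospitalization_cost",
    "hospitalization_cost_range", "hospitalization_prob",
    "community_response_cost", "operating_cost_by_period",
    "reported_total_operating_cost", "currency_year",
}
_LIFE_FIELDS = {"annual_income", "employment_rate",
                "median_age_at_death", "retirement_age"}


def _decimals_to_str(obj):
    if isinstance(obj, Decimal):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _decimals_to_str(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_decimals_to_str(v) for v in obj]
    return obj


def save_parameters(costs: CostParameters, life_value: LifeValueParameters,
                    path) -> None:
    """Write both parameter blocks to a YAML (or ``.json``) file."""
    payload = _decimals_to_str({"costs": asdict(costs),
                                "life_value": asdict(life_value)})
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_parameters(source) -> tuple[CostParameters, LifeValueParameters]:
    """Load parameters from a profile name or a YAML/JSON file.

    ``source`` may be a bundled profile name (``"nors2022"``) or a path to a
    file written by :func:`save_parameters`.  Raises :class:`ParameterError`
    naming the offending field on any invalid value, and on missing keys.
    """
    if isinstance(source, str) and source in _PROFILES:
        return _PROFILES[source]()
    path = Path(source)
    if not path.exists():
        raise ParameterError(f"source: no such profile or file: {source!r}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "costs" not in data or "life_value" not in data:
        raise ParameterError("file: expected top-level 'costs' and 'life_value' keys")
    for key in data["costs"]:
        _require(key in _COST_FIELDS, key, "unknown cost parameter")
    for key in data["life_value"]:
        _require(key in _LIFE_FIELDS, key, "unknown life-value parameter")
    costs = dict(data["costs"])
    for rng in ("ems_fee_range", "hospitalization_cost_range"):
        if rng in costs and costs[rng] is not None:
            costs[rng] = tuple(costs[rng])
    return CostParameters(**costs), LifeValueParameters(**data["life_value"])
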