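"""Medical-systems costing of overdose responses.

Each EMS-attended overdose is priced as ambulance fee + emergency-department
visit + physician assessment (inflation-adjusted) + one nasal naloxone kit +
the expected hospitalization cost (admission probability x admission cost).
False-positive EMS dispatches incur the ambulance fee only; a community-based
response costs one naloxone kit.  Components are rounded to cents half-up
only at the final per-component sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .call_log import ServiceTally
from .currency import D, cents
from .parameters import CostParameters

__all__ = [
    "CostBreakdown", "per_ems_overdose_cost", "medical_services_cost",
    "false_positive_cost", "community_savings",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Per-period cost decomposition; ``medical_cost`` is the component sum."""

    period: str
    operating_cost: Decimal
    medical_cost: Decimal
    ambulance_component: Decimal
    ed_component: Decimal            # ED visit + physician + naloxone per EMS overdose
    hospitalization_component: Decimal
    false_positive_component: Decimal
    community_component: Decimal

    @property
    def total_cost(self) -> Decimal:
        return self.operating_cost + self.medical_cost


def per_ems_overdose_cost(params: CostParameters) -> Decimal:
    """Expected medical-systems cost of one EMS-attended overdose."""
    return (params.ems_fee + params.ed_visit_cost + params.physician_fee
            + params.naloxone_cost
            + params.hospitalization_prob * params.hospitalization_cost)


def medical_services_cost(tally: ServiceTally,
                          params: CostParameters) -> CostBreakdown:
    """Total medical-services cost (TMSc) for one period's tally.

    Non-overdose EMS call-outs are tallied upstream but carry no cost here;
    the model prices overdose-pathway events only.
    """
    t_ems = D(tally.t_od)  # hospital-pathway count; defaults to t_ems upstream
    ambulance = cents(t_ems * params.ems_fee)
    ed = cents(t_ems * (params.ed_visit_cost + params.physician_fee
                        + params.naloxone_cost))
    hospitalization = cents(
        t_ems * params.hospitalization_prob * params.hospitalization_cost)
    false_positive = cents(D(tally.t_fc) * params.ems_fee)
    community = cents(D(tally.t_cr) * params.community_response_cost)
    medical = ambulance + ed + hospitalization + false_positive + community
    operating = params.operating_cost_by_period.get(tally.period, D(0))
    return CostBreakdown(
        period=tally.period,
        operating_cost=cents(operating),
        medical_cost=medical,
        ambulance_component=ambulance,
        ed_component=ed,
        hospitalization_component=hospitalization,
        false_positive_component=false_positive,
        community_component=community,
    )


def false_positive_cost(tally: ServiceTally, params: CostParameters) -> Decimal:
    """System cost of false-positive EMS dispatches (ambulance fee each)."""
    return cents(D(tally.t_fc) * params.ems_fee)


def community_savings(n_community: int,
                      params: CostParameters) -> tuple[Decimal, Decimal]:
    """Savings from community responses relative to EMS responses.

    Returns ``(per_response, total)`` where ``per_response`` is the expected
    EMS-pathway cost minus the cost of a community response, and ``total``
    scales it by the number of community-based overdose responses.
    """
    if n_community < 0:
        raise ValueError("n_community must be >= 0")
    per_response = cents(per_ems_overdose_cost(params)
                         - params.community_response_cost)
    return per_response, cents(D(n_community) * per_response)
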