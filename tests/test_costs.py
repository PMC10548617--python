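"""Medical-systems costing: unit prices, TMSc, linearity, pricing oracle."""

from dataclasses import replace
from decimal import Decimal

import pytest

from norscba import (
    CostParameters,
    Response,
    community_savings,
    false_positive_cost,
    medical_services_cost,
    per_ems_overdose_cost,
    tally,
)
from norscba.call_log import ServiceTally
from norscba.currency import D, cents

ZERO = CostParameters(
    ems_fee=0, ems_fee_range=(0, 0), ed_visit_cost=0, physician_fee_base=0,
    physician_fee=0, naloxone_cost=0, hospitalization_cost=0,
    hospitalization_cost_range=(0, 0), hospitalization_prob=0,
    operating_cost_by_period={})


def make_tally(t_ems=0, t_fc=0, t_cr=0, period="Funded 1"):
    n_od = t_ems + t_cr
    return ServiceTally(period=period, n_overdoses_total=n_od,
                        t_ems=t_ems, t_fc=t_fc, t_cr=t_cr, t_od=t_ems)


def test_per_ems_overdose_cost(nors_params):
    costs, _ = nors_params
    assert cents(per_ems_overdose_cost(costs)) == D("4475.82")
    assert per_ems_overdose_cost(ZERO) == 0
    no_admit = replace(costs, hospitalization_prob=0)
    assert cents(per_ems_overdose_cost(no_admit)) == D("1900.83")


@pytest.mark.parametrize("t_ems, t_fc, t_cr, expected", [
    (36, 2, 9, "163290.52"),   # first funded period
    (13, 0, 2, "58435.66"),    # second funded period
    (0, 0, 0, "0.00"),
])
def test_medical_services_cost_published_values(nors_params, t_ems, t_fc,
                                                t_cr, expected):
    costs, _ = nors_params
    b = medical_services_cost(make_tally(t_ems, t_fc, t_cr), costs)
    assert b.medical_cost == Decimal(expected)
    assert b.medical_cost == (b.ambulance_component + b.ed_component
                              + b.hospitalization_component
                              + b.false_positive_component
                              + b.community_component)


def test_medical_cost_linear_in_each_count(nors_params):
    """Doubling one count doubles its components only."""
    costs, _ = nors_params
    base = medical_services_cost(make_tally(10, 4, 6), costs)
    double_ems = medical_services_cost(make_tally(20, 4, 6), costs)
    assert double_ems.ambulance_component == 2 * base.ambulance_component
    assert double_ems.ed_component == 2 * base.ed_component
    assert double_ems.hospitalization_component == 2 * base.hospitalization_component
    assert double_ems.false_positive_component == base.false_positive_component
    assert double_ems.community_component == base.community_component
    double_fc = medical_services_cost(make_tally(10, 8, 6), costs)
    assert double_fc.false_positive_component == 2 * base.false_positive_component
    assert double_fc.ambulance_component == base.ambulance_component


def test_medical_cost_matches_record_level_pricing_oracle(nors_params,
                                                          fixture_records,
                                                          fixture_tallies):
    """Pricing each call individually and summing gives the same TMSc."""
    costs, _ = nors_params
    per_ems = per_ems_overdose_cost(costs)
    for period, t in fixture_tallies.items():
        total = D(0)
        for r in fixture_records:
            if r.period != period:
                continue
            if r.overdose and r.response is Response.EMS:
                total += per_ems
            elif r.overdose and r.response is Response.COMMUNITY:
                total += costs.community_response_cost
            elif r.false_positive_ems:
                total += costs.ems_fee
        assert cents(total) == medical_services_cost(t, costs).medical_cost


def test_reduces_to_ambulance_plus_community_when_other_costs_vanish():
    params = CostParameters(
        ems_fee=518, ems_fee_range=(518, 518), ed_visit_cost=0,
        physician_fee_base=0, physician_fee=0, naloxone_cost=0,
        community_response_cost=125, hospitalization_cost=0,
        hospitalization_cost_range=(0, 0), hospitalization_prob=0,
        operating_cost_by_period={})
    b = medical_services_cost(make_tally(7, 3, 2), params)
    assert b.medical_cost == D(518) * (7 + 3) + D(125) * 2


@pytest.mark.parametrize("t_fc, fee, expected", [
    (2, "518", "1036.00"),   # published false-positive system cost
    (0, "518", "0.00"),
    (3, "240", "720.00"),
])
def test_false_positive_cost(t_fc, fee, expected):
    params = CostParameters(ems_fee=fee, ems_fee_range=(fee, fee),
                            operating_cost_by_period={})
    assert false_positive_cost(make_tally(t_fc=t_fc), params) == Decimal(expected)


def test_community_savings(nors_params):
    costs, _ = nors_params
    per_response, total = community_savings(11, costs)
    assert per_response == D("4350.82")
    assert total == D("47859.02")
    assert community_savings(0, costs)[1] == 0
    equal = replace(costs, community_response_cost=per_ems_overdose_cost(costs))
    assert community_savings(1, equal) == (D("0.00"), D("0.00"))
    with pytest.raises(ValueError):
        community_savings(-1, costs)
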