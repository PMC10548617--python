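"""Model/Results facade over the cost-benefit pipeline.

:class:`OverdoseMonitoringCBA` binds a tallied call log to economic and
mortality parameters; :meth:`~OverdoseMonitoringCBA.fit` evaluates the full
cost-benefit analysis and returns a :class:`CBAResults` carrying per-period
and total outcomes, a text ``summary()``, DataFrame exports, and methods for
the Monte Carlo and sensitivity analyses.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from . import benefits, costs, uncertainty
from .benefits import CbaResult, MortalityAssumption
from .call_log import CallRecord, ServiceTally, combine_tallies, read_call_log, tally
from .costs import CostBreakdown
from .currency import D, cents, money
from .parameters import CostParameters, LifeValueParameters, load_parameters
from .synthetic import GeneratorConfig, generate_call_log, nors_fixture
from .uncertainty import MonteCarloSpec, SensitivityGrid

__all__ = ["OverdoseMonitoringCBA", "CBAResults"]

_TABLE2_POPULATIONS = tuple(range(10_000, 0, -1_000))
_TABLE2_PI = tuple(D(p) / 1000 for p in range(8))          # 0% .. 0.7%
_TABLE6_MULTIPLIERS = tuple(D(m) / 100 for m in range(200, 20, -20))
_TABLE6_PN = (D("0.08"), D("0.10"), D("0.20"), D("0.30"), D("0.40"),
              D("0.45"), D("0.50"), D("0.60"), D("0.70"), D("0.80"))


class OverdoseMonitoringCBA:
    """Cost-benefit model of a virtual overdose monitoring service.

    Parameters
    ----------
    tallies : mapping of period label to ServiceTally
        Per-period service counts (typically from :func:`norscba.call_log.tally`).
    cost_params, life_params : economic parameter objects
        Default to the bundled ``nors2022`` profile.
    mortality : MortalityAssumption
        Counterfactual death probabilities; base case Pn = 0.45, Pi = 0.
    include_unknown_callers : bool
        Count unknown-caller overdose events in the population N (the
        conservative default excludes them).
    use_reported_operating_total : bool
        Replace the summed per-period operating budgets with the separately
        reported total figure in the combined-total row only.
    """

    def __init__(self, tallies, cost_params: CostParameters | None = None,
                 life_params: LifeValueParameters | None = None,
                 mortality: MortalityAssumption | None = None, *,
                 include_unknown_callers: bool = False,
                 use_reported_operating_total: bool = False):
        if cost_params is None or life_params is None:
            default_costs, default_life = load_parameters("nors2022")
            cost_params = cost_params or default_costs
            life_params = life_params or default_life
        self.tallies: dict[str, ServiceTally] = dict(tallies)
        self.cost_params = cost_params
        self.life_params = life_params
        self.mortality = mortality or MortalityAssumption()
        self.include_unknown_callers = include_unknown_callers
        self.use_reported_operating_total = use_reported_operating_total

    @classmethod
    def from_call_log(cls, source, periods=None, **kwargs) -> "OverdoseMonitoringCBA":
        """Build from a CSV path or a sequence of :class:`CallRecord`."""
        if isinstance(source, str) or hasattr(source, "read_text"):
            records = read_call_log(source)
        else:
            records = list(source)
        return cls(tally(records, periods), **kwargs)

    @classmethod
    def from_fixture(cls, **kwargs) -> "OverdoseMonitoringCBA":
        """Build from the bundled deterministic fixture log."""
        return cls(tally(nors_fixture()), **kwargs)

    @classmethod
    def from_synthetic(cls, config: GeneratorConfig | None = None,
                       **kwargs) -> "OverdoseMonitoringCBA":
        """Build from a freshly generated synthetic log."""
        return cls(tally(generate_call_log(config or GeneratorConfig())), **kwargs)

    def _population(self, t: ServiceTally) -> int:
        n = t.n_overdoses_unique
        if self.include_unknown_callers:
            n += t.n_overdoses_unknown
        return n

    def fit(self) -> "CBAResults":
        """Evaluate the cost-benefit analysis for every period and the total."""
        vol = benefits.value_of_one_life(self.life_params)
        py = benefits.productive_years(self.life_params)
        pn = self.mortality.p_unwitnessed
        pn_lo, pn_hi = self.mortality.pn_range
        breakdowns: dict[str, CostBreakdown] = {}
        rows: list[CbaResult] = []
        for period, t in self.tallies.items():
            breakdowns[period] = costs.medical_services_cost(t, self.cost_params)
            rows.append(self._evaluate(t, breakdowns[period], vol, py))
        total_tally = combine_tallies(self.tallies)
        total_breakdown = costs.medical_services_cost(total_tally, self.cost_params)
        operating_total = sum((b.operating_cost for b in breakdowns.values()), D(0))
        if self.use_reported_operating_total and \
                self.cost_params.reported_total_operating_cost is not None:
            operating_total = self.cost_params.reported_total_operating_cost
        total_breakdown = CostBreakdown(
            period=total_tally.period, operating_cost=operating_total,
            medical_cost=total_breakdown.medical_cost,
            ambulance_component=total_breakdown.ambulance_component,
            ed_component=total_breakdown.ed_component,
            hospitalization_component=total_breakdown.hospitalization_component,
            false_positive_component=total_breakdown.false_positive_component,
            community_component=total_breakdown.community_component,
        )
        breakdowns[total_tally.period] = total_breakdown
        total_row = self._evaluate(total_tally, total_breakdown, vol, py)
        return CBAResults(self, rows, total_row, breakdowns, vol, py)

    def _evaluate(self, t: ServiceTally, breakdown: CostBreakdown,
                  vol: Decimal, py: Decimal) -> CbaResult:
        n = self._population(t)
        pn = self.mortality.p_unwitnessed
        averted = benefits.deaths_averted(n, self.mortality)
        value = benefits.value_of_deaths_averted(n, pn, vol)
        v_lo, v_hi = (benefits.value_of_deaths_averted(n, p, vol)
                      for p in self.mortality.pn_range)
        op, med = breakdown.operating_cost, breakdown.medical_cost
        nb = benefits.net_benefit(value, op, med)
        nb_range = tuple(benefits.net_benefit(v, op, med) for v in (v_lo, v_hi))
        if op + med > 0:
            ratio = benefits.benefit_cost_ratio(value, op, med)
            ratio_range = tuple(benefits.benefit_cost_ratio(v, op, med)
                                for v in (v_lo, v_hi))
        else:
            ratio, ratio_range = D("NaN"), (D("NaN"), D("NaN"))
        if averted > 0:
            life_years, cost_per_ly = benefits.life_years_and_cost_per_life_year(
                averted, vol, py)
        else:
            life_years, cost_per_ly = D(0), D("NaN")
        return CbaResult(
            period=t.period, n_unique_overdoses=n, deaths_averted=averted,
            value_of_life=vol, value_of_deaths_averted=value,
            value_range=(v_lo, v_hi), operating_cost=op, medical_cost=med,
            net_benefit=nb, net_benefit_range=nb_range, bc_ratio=ratio,
            bc_ratio_range=ratio_range, life_years_saved=life_years,
            cost_per_life_year=cost_per_ly,
        )


class CBAResults:
    """Fitted cost-benefit results with uncertainty and sensitivity methods."""

    def __init__(self, model: OverdoseMonitoringCBA, by_period: list[CbaResult],
                 total: CbaResult, breakdowns: dict[str, CostBreakdown],
                 value_of_life: Decimal, productive_years: Decimal):
        self.model = model
        self.by_period = by_period
        self.total = total
        self.cost_breakdowns = breakdowns
        self.value_of_life = value_of_life
        self.productive_years = productive_years

    # ---- exports -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Main results table (one row per period plus the total), floats."""
        rows = []
        for r in [*self.by_period, self.total]:
            rows.append({
                "period": r.period, "n_unique_overdoses": r.n_unique_overdoses,
                "deaths_averted": float(r.deaths_averted),
                "value_of_deaths_averted": float(r.value_of_deaths_averted),
                "value_low": float(r.value_range[0]),
                "value_high": float(r.value_range[1]),
                "operating_cost": float(r.operating_cost),
                "medical_cost": float(r.medical_cost),
                "net_benefit": float(r.net_benefit),
                "net_benefit_low": float(r.net_benefit_range[0]),
                "net_benefit_high": float(r.net_benefit_range[1]),
                "bc_ratio": float(_round2(r.bc_ratio)),
                "bc_ratio_low": float(_round2(r.bc_ratio_range[0])),
                "bc_ratio_high": float(_round2(r.bc_ratio_range[1])),
            })
        return pd.DataFrame(rows).set_index("period")

    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        m = self.model.mortality
        lines = [
            "Virtual overdose monitoring service cost-benefit analysis",
            "=" * 58,
            f"Value of one life (human capital): {money(self.value_of_life)}"
            f"  ({self.productive_years} productive years)",
            f"Mortality assumption: Pn={m.p_unwitnessed}"
            f" (range {m.pn_range[0]}-{m.pn_range[1]}), Pi={m.p_on_service}",
            "",
            f"{'period':<12}{'N':>4}{'value averted':>16}{'operating':>14}"
            f"{'medical':>12}{'net benefit':>16}{'B/C':>7}",
        ]
        for r in [*self.by_period, self.total]:
            lines.append(
                f"{r.period:<12}{r.n_unique_overdoses:>4}"
                f"{float(r.value_of_deaths_averted):>16,.2f}"
                f"{float(r.operating_cost):>14,.2f}"
                f"{float(r.medical_cost):>12,.2f}"
                f"{float(r.net_benefit):>16,.2f}"
                f"{float(_round2(r.bc_ratio)):>7.2f}"
            )
        lo, hi = (_round2(x) for x in self.total.bc_ratio_range)
        lines += [
            "",
            f"Headline benefit-to-cost ratio: {_round2(self.total.bc_ratio)}"
            f" (range {lo}-{hi}) per dollar spent",
            f"Break-even unwitnessed-overdose mortality: "
            f"{float(self.break_even_mortality()):.4f}",
        ]
        return "\n".join(lines)

    # ---- uncertainty & sensitivity ----------------------------------

    def monte_carlo(self, spec: MonteCarloSpec | None = None,
                    n: int | None = None) -> uncertainty.MonteCarloSummary:
        """Monte Carlo over Pn for the total population (overridable ``n``)."""
        spec = spec or MonteCarloSpec()
        return uncertainty.monte_carlo_mortality(
            spec, n if n is not None else self.total.n_unique_overdoses,
            self.value_of_life)

    def deaths_averted_grid(self, populations=_TABLE2_POPULATIONS,
                            pi_values=_TABLE2_PI, pn=None) -> SensitivityGrid:
        """Scaling grid: deaths averted across service size and Pi."""
        return uncertainty.deaths_averted_grid(
            populations, pi_values,
            pn if pn is not None else self.model.mortality.p_unwitnessed)

    def two_way_sensitivity(self, cost_multipliers=_TABLE6_MULTIPLIERS,
                            pn_values=_TABLE6_PN) -> SensitivityGrid:
        """Two-way grid: net benefit and ratio across operating-budget scale
        and unwitnessed-overdose mortality."""
        return uncertainty.two_way_sensitivity(
            self.total.n_unique_overdoses, self.value_of_life,
            self.total.operating_cost, self.total.medical_cost,
            cost_multipliers, pn_values)

    def break_even_mortality(self) -> Decimal:
        """Pn at which total value of deaths averted equals total cost."""
        return uncertainty.break_even_mortality(
            self.total.total_cost, self.total.n_unique_overdoses,
            self.value_of_life)

    def community_savings(self) -> tuple[Decimal, Decimal]:
        """(per-response, total) savings from community-based responses."""
        t_cr = sum(t.t_cr for t in self.model.tallies.values())
        return costs.community_savings(t_cr, self.model.cost_params)

    def life_years_table(self, deaths_by_period: dict[str, int]) -> pd.DataFrame:
        """Life-years saved and cost per life-year for given prevented-death
        counts (accepted as direct inputs), plus their total."""
        rows = []
        items = list(deaths_by_period.items())
        items.append(("Total", sum(deaths_by_period.values())))
        for label, deaths in items:
            ly, cost_per_ly = benefits.life_years_and_cost_per_life_year(
                deaths, self.value_of_life, self.productive_years)
            rows.append({
                "period": label, "deaths_prevented": deaths,
                "value_of_prevented_deaths":
                    float(cents(D(deaths) * self.value_of_life)),
                "life_years_saved": float(ly),
                "cost_per_life_year": float(cost_per_ly),
            })
        return pd.DataFrame(rows).set_index("period")


def _round2(x: Decimal) -> Decimal:
    if x.is_nan():
        return x
    return x.quantize(D("0.01"), rounding=ROUND_HALF_UP)
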