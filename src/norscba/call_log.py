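"""Service call-log data model, CSV I/O and per-period tallying.

A call log has one row per call to the monitoring line.  Tallying reduces it
to the per-period counts the cost and benefit models consume: EMS call-outs
for overdoses (``t_ems``), false-positive EMS call-outs (``t_fc``),
community-based responses (``t_cr``) and the unique / unknown overdose-caller
counts that define the population N for the deaths-averted calculation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, fields
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Category", "Response", "CallRecord", "ServiceTally", "CallLogError",
    "read_call_log", "write_call_log", "tally", "combine_tallies",
]


class Category(str, enum.Enum):
    SUBSTANCE_USE = "substance_use"
    MENTAL_HEALTH = "mental_health"
    REFERRAL = "referral"
    OTHER = "other"


class Response(str, enum.Enum):
    NONE = "none"
    EMS = "ems"
    COMMUNITY = "community"


class CallLogError(ValueError):
    """Malformed call-log content; messages carry 1-based line numbers."""


@dataclass(frozen=True)
class CallRecord:
    """One operator-logged call.

    ``caller_id`` is ``None`` when the operator could not ascribe a caller
    code (an "unknown" caller).  A non-``none`` response requires a reason:
    an overdose, a false-positive EMS dispatch, or a non-overdose emergency.
    """

    timestamp: datetime
    period: str
    category: Category
    overdose: bool = False
    caller_id: str | None = None
    response: Response = Response.NONE
    false_positive_ems: bool = False
    non_overdose_emergency: bool = False

    def __post_init__(self):
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "response", Response(self.response))
        if self.response is not Response.NONE and not (
            self.overdose or self.false_positive_ems or self.non_overdose_emergency
        ):
            raise CallLogError(
                "response requires an overdose, false-positive or "
                "non-overdose emergency flag"
            )
        if self.false_positive_ems and self.response is not Response.EMS:
            raise CallLogError("false_positive_ems implies response = ems")


@dataclass(frozen=True)
class ServiceTally:
    """Per-period counts feeding the cost and benefit models."""

    period: str
    n_calls: int = 0
    n_substance_calls: int = 0
    n_mh_calls: int = 0
    n_referrals: int = 0
    n_overdoses_total: int = 0
    n_overdoses_unique: int = 0      # distinct caller_ids with >= 1 overdose
    n_overdoses_unknown: int = 0     # overdose events with no caller_id
    t_ems: int = 0                   # EMS call-outs for overdoses
    t_fc: int = 0                    # false-positive EMS call-outs
    t_cr: int = 0                    # community-based overdose responses
    t_od: int = 0                    # overdoses on the hospital pathway (= t_ems)
    n_ems_non_od: int = 0            # EMS call-outs for non-overdose emergencies

    def __post_init__(self):
        for f in fields(self):
            if f.name == "period":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise CallLogError(f"{f.name}: counts must be non-negative integers")
        if self.t_ems + self.t_cr > self.n_overdoses_total:
            raise CallLogError("t_ems + t_cr cannot exceed n_overdoses_total")
        if self.n_overdoses_unique + self.n_overdoses_unknown > self.n_overdoses_total:
            raise CallLogError(
                "n_overdoses_unique + n_overdoses_unknown cannot exceed total"
            )


_COLUMNS = ["timestamp", "period", "category", "overdose", "caller_id",
            "response", "false_positive_ems", "non_overdose_emergency"]
_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def write_call_log(records: Iterable[CallRecord], path) -> None:
    """Write records as UTF-8 CSV with ISO-8601 timestamps."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow([
                r.timestamp.isoformat(), r.period, r.category.value,
                str(r.overdose).lower(), r.caller_id or "",
                r.response.value, str(r.false_positive_ems).lower(),
                str(r.non_overdose_emergency).lower(),
            ])


def read_call_log(path) -> list[CallRecord]:
    """Read and validate a call-log CSV; errors name the offending line."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise CallLogError(f"{path.name}: missing required columns {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(CallRecord(
                    timestamp=datetime.fromisoformat(row["timestamp"]),
                    period=row["period"],
                    category=Category(row["category"]),
                    overdose=_parse_bool(row["overdose"], "overdose"),
                    caller_id=row["caller_id"] or None,
                    response=Response(row["response"]),
                    false_positive_ems=_parse_bool(
                        row["false_positive_ems"], "false_positive_ems"),
                    non_overdose_emergency=_parse_bool(
                        row["non_overdose_emergency"], "non_overdose_emergency"),
                ))
            except (ValueError, KeyError) as exc:
                raise CallLogError(f"{path.name}, line {lineno}: {exc}") from exc
    return records


def _parse_bool(text: str, field_name: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ValueError(f"{field_name}: not a boolean: {text!r}") from None


def tally(records: Sequence[CallRecord],
          periods: Sequence[str] | None = None) -> dict[str, ServiceTally]:
    """Reduce a call log to one :class:`ServiceTally` per period.

    ``periods`` fixes the output order and must cover every record's period;
    when omitted, periods are taken in order of first appearance.  Caller
    uniqueness is evaluated within each period independently, so the
    population N used downstream is the sum of per-period unique counts.
    """
    if periods is None:
        periods = list(dict.fromkeys(r.period for r in records))
    periods = list(periods)
    unlisted = {r.period for r in records} - set(periods)
    if unlisted:
        raise CallLogError(f"records reference unlisted periods: {sorted(unlisted)}")

    out: dict[str, ServiceTally] = {}
    for period in periods:
        rows = [r for r in records if r.period == period]
        od = [r for r in rows if r.overdose]
        unique_ids = {r.caller_id for r in od if r.caller_id is not None}
        t_ems = sum(1 for r in od if r.response is Response.EMS)
        out[period] = ServiceTally(
            period=period,
            n_calls=len(rows),
            n_substance_calls=sum(1 for r in rows
                                  if r.category is Category.SUBSTANCE_USE),
            n_mh_calls=sum(1 for r in rows if r.category is Category.MENTAL_HEALTH),
            n_referrals=sum(1 for r in rows if r.category is Category.REFERRAL),
            n_overdoses_total=len(od),
            n_overdoses_unique=len(unique_ids),
            n_overdoses_unknown=sum(1 for r in od if r.caller_id is None),
            t_ems=t_ems,
            t_fc=sum(1 for r in rows if r.false_positive_ems),
            t_cr=sum(1 for r in od if r.response is Response.COMMUNITY),
            t_od=t_ems,
            n_ems_non_od=sum(1 for r in rows if r.non_overdose_emergency
                             and r.response is Response.EMS),
        )
    return out


def combine_tallies(tallies: Mapping[str, ServiceTally],
                    label: str = "Total") -> ServiceTally:
    """Column-wise sum of per-period tallies (unique counts sum per period)."""
    sums = {f.name: sum(getattr(t, f.name) for t in tallies.values())
            for f in fields(ServiceTally) if f.name != "period"}
    return ServiceTally(period=label, **sums)
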