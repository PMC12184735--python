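"""Audit statistics over an alert log.

Computes the reporting surface a unit reviews when tuning its alert policy:
daily alert counts with mean and range, an acknowledgement frequency table
with clinical-report-style percentages, and per-criterion attribution.

Percentage display rule: round half up to an integer; when a nonzero count
rounds to 0 the cell shows ``"<1"`` rather than a misleading zero.  Daily
bucketing uses calendar days in a configured reporting timezone (default
UTC); partial first and last days count as full days in the denominator, and
zero-alert days are included in both the mean and the range.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union
from zoneinfo import ZoneInfo

from .acknowledgement import AckLabel, DISPLAY, close_unacknowledged
from .alert_engine import AlertEvent, PhaseConfig, detect
from .vitals_io import Parameter, VitalStream

PathLike = Union[str, Path]


def format_percent(count: int, total: int) -> str:
    """Integer percentage, rounded half up; ``"<1"`` for nonzero counts that round to 0."""
    if total <= 0 or count == 0:
        return "0"
    pct = Decimal(100 * count) / Decimal(total)
    rounded = int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if rounded == 0:
        return "<1"
    return str(rounded)


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal("1") if decimals == 0 else Decimal("0." + "0" * (decimals - 1) + "1")
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AckCell:
    count: int
    percent: str  # display string per the rounding rule


@dataclass(frozen=True)
class AuditReport:
    """Audit summary over a reporting period."""

    period: tuple[datetime, datetime]
    timezone: str
    n_alerts: int
    n_days: int
    alerts_per_day_mean: float  # n_alerts / n_days, shown to 1 decimal
    alerts_per_day_range: tuple[int, int]
    ack_table: dict[AckLabel, AckCell]
    criterion_attribution: dict[Parameter, float]

    def to_dict(self) -> dict:
        return {
            "period": [self.period[0].isoformat(), self.period[1].isoformat()],
            "timezone": self.timezone,
            "n_alerts": self.n_alerts,
            "n_days": self.n_days,
            "alerts_per_day_mean": self.alerts_per_day_mean,
            "alerts_per_day_range": list(self.alerts_per_day_range),
            "ack_table": {
                label.value: {
                    "display": DISPLAY[label],
                    "count": cell.count,
                    "percent": cell.percent,
                }
                for label, cell in self.ack_table.items()
            },
            "criterion_attribution": {
                p.value: frac for p, frac in self.criterion_attribution.items()
            },
        }

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def build_report(
    alerts: Sequence[AlertEvent],
    period: tuple[datetime, datetime],
    tz: str = "UTC",
) -> AuditReport:
    """Compute the audit report for a closed alert log.

    Every alert must fall inside ``period`` and carry an acknowledgement
    outcome (run :func:`emews.acknowledgement.close_unacknowledged` first).
    """
    start, end = period
    if start > end:
        raise ValueError("period start must not be after its end")
    zone = ZoneInfo(tz)
    for a in alerts:
        if a.acknowledgement is None:
            raise ValueError(
                f"open alert for {a.patient_id} at {a.fired_at.isoformat()}; "
                "close_unacknowledged must run before reporting"
            )
        if not (start <= a.fired_at <= end):
            raise ValueError(
                f"alert at {a.fired_at.isoformat()} lies outside the report period"
            )

    start_day = start.astimezone(zone).date()
    end_day = end.astimezone(zone).date()
    n_days = (end_day - start_day).days + 1
    daily = {start_day + timedelta(days=i): 0 for i in range(n_days)}
    for a in alerts:
        daily[a.fired_at.astimezone(zone).date()] += 1

    n_alerts = len(alerts)
    counts = {label: 0 for label in AckLabel}
    for a in alerts:
        counts[a.acknowledgement.label] += 1
    ack_table = {
        label: AckCell(count=c, percent=format_percent(c, n_alerts))
        for label, c in counts.items()
    }

    attribution: dict[Parameter, float] = {}
    if n_alerts:
        for p in Parameter:
            k = sum(1 for a in alerts if p in a.parameters())
            if k:
                attribution[p] = k / n_alerts

    day_counts = list(daily.values())
    return AuditReport(
        period=(start, end),
        timezone=tz,
        n_alerts=n_alerts,
        n_days=n_days,
        alerts_per_day_mean=round_half_up(n_alerts / n_days, 1),
        alerts_per_day_range=(min(day_counts), max(day_counts)) if day_counts else (0, 0),
        ack_table=ack_table,
        criterion_attribution=attribution,
    )


def compare_phases(
    stream: VitalStream,
    policies: Sequence[PhaseConfig],
    period: Optional[tuple[datetime, datetime]] = None,
    tz: str = "UTC",
) -> list[AuditReport]:
    """Run the engine under several policies on one stream; report each.

    Alerts are auto-closed as NOT_ACKNOWLEDGED for reporting.  When no
    period is given it spans the stream's first to last sample.
    """
    if period is None:
        if len(stream) == 0:
            raise ValueError("cannot infer a report period from an empty stream")
        times = [s.timestamp for s in stream]
        period = (min(times), max(times))
    reports = []
    for policy in policies:
        alerts = detect(stream, policy)
        alerts = close_unacknowledged(alerts, horizon=period[1])
        reports.append(build_report(alerts, period, tz=tz))
    return reports
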