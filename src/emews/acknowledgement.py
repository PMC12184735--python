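"""Nurse-facing alert acknowledgement workflow.

When an alert pop-up is validated in the EMR, the nurse chooses one of four
responses; an alert that never receives one is closed as not acknowledged at
audit time.  Exactly five outcome labels exist, and the audit module
partitions every alert into exactly one of them.

There is no timeout model for when an open alert becomes NOT_ACKNOWLEDGED —
closure is an explicit audit-time operation with a horizon
(:func:`close_unacknowledged`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Optional, Sequence

from .alert_engine import AlertEvent


class AckLabel(str, Enum):
    """The five acknowledgement outcomes.  Values are the alert-log CSV labels."""

    MD_AWARE_ONGOING = "md_aware_ongoing"
    WILL_NOTIFY_MD = "will_notify_md"
    TREATMENT_PROVIDED = "treatment_provided"
    NOT_PROVIDING_CARE = "not_providing_care"
    NOT_ACKNOWLEDGED = "not_acknowledged"


#: Default display wording for each outcome.
DISPLAY: dict[AckLabel, str] = {
    AckLabel.MD_AWARE_ONGOING: "MD aware, ongoing monitoring",
    AckLabel.WILL_NOTIFY_MD: "Will notify MD",
    AckLabel.TREATMENT_PROVIDED: "Treatment provided, ongoing monitoring",
    AckLabel.NOT_PROVIDING_CARE: "Not providing direct care",
    AckLabel.NOT_ACKNOWLEDGED: "Alert not acknowledged",
}

#: Alternate wording seen in audit tables for the first option.  One
#: canonical enum member carries both display strings so the data model
#: stays consistent.
ALT_DISPLAY: dict[AckLabel, str] = {
    AckLabel.MD_AWARE_ONGOING: "MD aware, ongoing treatment",
}


@dataclass(frozen=True)
class AckOutcome:
    """Acknowledgement outcome of one alert.

    ``acknowledged_at`` is set by :func:`acknowledge`; outcomes loaded from
    alert-log CSVs carry None because the log format does not retain
    acknowledgement latency.
    """

    label: AckLabel
    acknowledged_at: Optional[datetime] = None


class AcknowledgementStateError(RuntimeError):
    """An alert was acknowledged twice."""


def acknowledge(alert: AlertEvent, label: AckLabel, at: datetime) -> AlertEvent:
    """Attach a nurse's response to an open alert.

    An alert can be acknowledged exactly once, at or after the time it
    fired, and only with one of the four active response options.
    """
    if alert.acknowledgement is not None:
        raise AcknowledgementStateError(
            f"alert for {alert.patient_id} at {alert.fired_at.isoformat()} "
            "is already acknowledged"
        )
    label = AckLabel(label)
    if label is AckLabel.NOT_ACKNOWLEDGED:
        raise ValueError("NOT_ACKNOWLEDGED is assigned by close_unacknowledged, not a nurse response")
    if at < alert.fired_at:
        raise ValueError("acknowledgement time precedes the alert's firing time")
    return dataclasses.replace(alert, acknowledgement=AckOutcome(label=label, acknowledged_at=at))


def close_unacknowledged(alerts: Sequence[AlertEvent], horizon: datetime) -> list[AlertEvent]:
    """Label every still-open alert fired at or before ``horizon`` as NOT_ACKNOWLEDGED.

    Acknowledged alerts and alerts fired after the horizon are returned
    unchanged.
    """
    closed: list[AlertEvent] = []
    for a in alerts:
        if a.acknowledgement is None and a.fired_at <= horizon:
            closed.append(
                dataclasses.replace(
                    a, acknowledgement=AckOutcome(label=AckLabel.NOT_ACKNOWLEDGED)
                )
            )
        else:
            closed.append(a)
    return closed
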