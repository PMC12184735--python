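"""Acknowledge alerts and build the audit report a unit would review.

Detects alerts on a simulated ward, has a "nurse" respond to most of them,
closes the rest as not acknowledged, and prints the acknowledgement
frequency table with clinical-report-style percentages (integer, round half
up, with "<1" for nonzero counts that round to zero).
"""

from datetime import timedelta

from emews import (
    AckLabel,
    Phase,
    ScenarioMix,
    acknowledge,
    build_report,
    close_unacknowledged,
    default_policy,
    detect,
    scenario_battery,
    simulate_ward,
)
from emews.acknowledgement import DISPLAY

scenarios = scenario_battery(
    n_patients=25, mix=ScenarioMix(epidural=0.6, deterioration=0.2), seed=21,
    artifact_rate=0.06,
)
stream, _ = simulate_ward(scenarios, seed=21)
alerts = detect(stream, default_policy(Phase.P3))

# respond to alerts in a fixed rotation; leave every 11th unacknowledged
responses = [AckLabel.MD_AWARE_ONGOING, AckLabel.MD_AWARE_ONGOING,
             AckLabel.WILL_NOTIFY_MD, AckLabel.TREATMENT_PROVIDED,
             AckLabel.NOT_PROVIDING_CARE]
handled = []
for i, alert in enumerate(alerts):
    if i % 11 == 10:
        handled.append(alert)  # nurse never responds
    else:
        handled.append(acknowledge(alert, responses[i % len(responses)],
                                   at=alert.fired_at + timedelta(minutes=2)))

times = [s.timestamp for s in stream]
period = (min(times), max(times))
handled = close_unacknowledged(handled, horizon=period[1])
report = build_report(handled, period)

print(f"{report.n_alerts} alerts over {report.n_days} days "
      f"(mean {report.alerts_per_day_mean}/day, range {report.alerts_per_day_range})\n")
for label, cell in report.ack_table.items():
    print(f"  {DISPLAY[label]:<42} {cell.count:4d} ({cell.percent}%)")

# Counts always sum to the total; each percentage cell is what a clinical
# audit table would print for that row.
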