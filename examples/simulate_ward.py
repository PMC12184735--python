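"""Simulate a small labor ward and inspect the generated flowsheet.

Builds a 10-patient scenario battery (half with epidurals, one deteriorating),
simulates the monitoring cadences of an intrapartum unit, and prints what the
stream contains.  Monitor channels (BP, HR, SpO2) carry occasional artifact
spikes — movement and pushing — which the ground-truth sidecar labels.
"""

from emews import Parameter, ScenarioMix, Source, scenario_battery, simulate_ward

scenarios = scenario_battery(
    n_patients=10,
    mix=ScenarioMix(epidural=0.5, deterioration=0.1),
    seed=11,
    artifact_rate=0.05,
)
stream, truth = simulate_ward(scenarios, seed=11)

n_monitor = sum(1 for s in stream if s.source is Source.MONITOR)
print(f"patients:        {len(scenarios)}")
print(f"samples:         {len(stream)} ({n_monitor} monitor, {len(stream) - n_monitor} manual)")
print(f"artifacts:       {truth.n_artifacts()} "
      f"({truth.artifact_fraction():.1%} of monitor samples; configured 5%)")
for p in (Parameter.SBP, Parameter.HR, Parameter.TEMP):
    n = sum(1 for s in stream if s.parameter is p)
    print(f"  {p.value:<5} samples: {n}")

# The artifact fraction recovered from the labels should sit near the
# configured rate; each patient's sample count reflects their cadences
# (epidural patients log BP/HR every 15 minutes, so they dominate).
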