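"""Simulate and parse a fixed-ratio operant session.

Generates an FR5 session with a 5 s response limit and light delivered on 33%
of trials, parses the event log into trials with outcomes and latencies, and
prints the performance table split by light delivery.
"""

import numpy as np

from fiberphot import BehaviorSimConfig, parse_trials, session_performance
from fiberphot.behavior import meets_advancement_criterion, trials_to_frame
from fiberphot.synth import simulate_fr_session

cfg = BehaviorSimConfig(schedule="FR5-5s", n_trials=120, press_rate_hz=1.5,
                        p_engage=0.85, light_fraction=0.33, light_effect=-0.3,
                        seed=4)
log = simulate_fr_session(cfg)
trials = parse_trials(log, cfg.schedule)
frame = trials_to_frame(trials)

print(session_performance(trials).round(1))
completed = frame[frame.outcome == "completed"]
print(f"\nmedian initiation latency : {completed.initiation_latency_s.median():.2f} s")
print(f"median retrieval latency  : {completed.retrieval_latency_s.median():.2f} s")
n_completed = int((frame.outcome == "completed").sum())
print(f"advancement criterion met : "
      f"{meets_advancement_criterion([n_completed, n_completed])}")
# With light_effect < 0 the light stratum completes fewer trials and omits
# more - the direction of an inhibitory manipulation on this task.
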