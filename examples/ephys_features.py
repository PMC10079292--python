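"""Extract intrinsic-property features from simulated current-clamp sweeps.

Builds a family of depolarizing steps with an accommodating spike train, a
-140 pA step for input resistance, and a hyperpolarizing sweep with a rebound
burst, then runs the full feature battery.
"""

import numpy as np

from fiberphot import ephys
from fiberphot.synth import simulate_current_clamp

# decelerating train sustained across the 0.5 s step: intervals lengthen
isis = np.array([0.020, 0.024, 0.030, 0.040, 0.055, 0.075, 0.100, 0.125])
times = 0.225 + np.concatenate(([0.0], np.cumsum(isis)))
strong = simulate_current_clamp(times, step_pa=200.0, rin_mohm=110.0, seed=0)
weak = simulate_current_clamp([0.3, 0.4, 0.5], step_pa=80.0, rin_mohm=110.0, seed=1)
rin_sweep = simulate_current_clamp([], step_pa=-140.0, rin_mohm=110.0,
                                   noise_sd_mv=0.2, seed=2)
rebound = simulate_current_clamp([0.712, 0.730, 0.752], step_pa=-140.0,
                                 rin_mohm=110.0, seed=3)

f = ephys.extract_features([weak, strong], rin_sweep, rebound_sweep=rebound)
print(f"spikes on best step : {len(f.spike_times_s)}")
print(f"AP threshold        : {f.ap_threshold_mv:.1f} mV")
print(f"max firing rate     : {f.max_rate_hz:.1f} Hz (first six APs)")
print(f"accommodation index : {f.accommodation_index:+.3f}")
print(f"input resistance    : {f.input_resistance_mohm:.1f} MOhm")
print(f"rebound burst       : {f.rebound_n_aps} APs, "
      f"mean ISI {f.rebound_mean_isi_s * 1000:.1f} ms")
print(f"depolarization block: {f.excluded_depol_block}")
# Lengthening ISIs give a positive accommodation index; the -140 pA step
# recovers the 110 MOhm input resistance from the Ohmic deflection.
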