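"""Segment a lick train into bouts.

Builds a train with known bout structure plus a few isolated licks and runs
the bout rule: two or more licks with every inter-lick interval under 2 s.
"""

from fiberphot import detect_bouts
from fiberphot.synth import simulate_lick_train

licks = simulate_lick_train(n_bouts=4, licks_per_bout=6, intra_ili_s=0.18,
                            inter_bout_gap_s=8.0)
licks += [100.0, 110.0]  # isolated licks: never part of a bout
bouts = detect_bouts(sorted(licks))

print(f"licks in  : {len(licks)}")
print(f"bouts out : {len(bouts)}")
for b in bouts:
    print(f"  {b.start_s:6.1f} - {b.end_s:6.1f} s  ({b.n_licks} licks)")
# Four constructed bouts are recovered; the two isolated licks are discarded.
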