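"""Inter-coder reliability: event matching and phase-duration agreement.

Simulates a second coder by jittering every boundary of a generated
annotation set by 80 ms of normal noise, then measures (a) how many events
the two coders share within a 1-s onset/offset tolerance, and (b) the
percentage of opening-phase duration pairs within a 0.5-s tolerance.
"""

import yawndyn as yd

coder_a = yd.generate_dataset(15, 115, seed=7, gap=10.0)  # shared timeline
coder_b = yd.generate_coder_pair(coder_a, jitter_sd=0.08, seed=8)

events = yd.match_events(coder_a, coder_b, tolerance=1.0)
print(f"event matching: {len(events.matched)} of {len(coder_a)} matched "
      f"({events.percent_agreement:.0f}% agreement at 1-s tolerance)")

open_a = [e.plateau_onset - e.onset for e in coder_a]
open_b = [e.plateau_onset - e.onset for e in coder_b]
percent, median_diff = yd.phase_duration_agreement(open_a, open_b, tolerance=0.5)
print(f"opening-phase durations: {percent:.0f}% of pairs within 0.5 s, "
      f"median |difference| {median_diff:.3f} s")

kappa = yd.binned_kappa(coder_a, coder_b, fps=24)
print(f"frame-binned kappa over the shared timeline: {kappa:.2f}")
print("High values mean the two coders describe the same events with the")
print("same phase timing, up to small boundary placement noise.")
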