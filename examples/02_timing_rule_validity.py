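"""Construct validity of the timing rule against reference labels.

Generates a 130-episode sample with the study's class structure (15 yawns,
115 non-yawn mouth openings), applies the timing rule (yawn iff time to
maximum opening strictly exceeds closing time) and prints the 2x2
contingency analysis against the reference labels. The rule's sensitivity
is always 1.0 on generated yawns — their phase-duration bounds force
opening + plateau > closing — while specificity is poor, because many
non-yawn openings also satisfy the rule.
"""

import yawndyn as yd

dataset = yd.generate_dataset(n_yawn=15, n_non_yawn=115, seed=42)
report = yd.run_study1(dataset)
print(report.to_markdown())
print()
print("Interpretation: sensitivity is the fraction of reference yawns the")
print("rule recovers; specificity the fraction of non-yawns it rejects.")
print("Kappa corrects the raw agreement for chance.")
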