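"""Tune and compare the two SVM feature sets by repeated hold-out.

Model A uses all five temporal variables (total, plateau and opening
durations, opening/closing asymmetry and ratio); Model B only total
duration, plateau duration and asymmetry. Hyperparameters (C, gamma) are
tuned once by 10-fold grid search over [1e-3, 1e3]; each model is then
evaluated on 200 random 87/43 train/test splits and ranked by mean
Cohen's kappa.
"""

import yawndyn as yd

dataset = yd.generate_dataset(15, 115, seed=11)
config = yd.HoldoutConfig(
    n_iterations=200, tuning_mode="tune_once_full_data", seed=12
)
report = yd.run_study2(dataset, config=config)

print(report.ranking.round(3))
print()
for name, (C, gamma) in report.tuned.items():
    print(f"model {name}: tuned C={C}, gamma={gamma}")
print()
print("mean_kappa is chance-corrected test-set agreement averaged over the")
print("200 splits; the top row is the preferred model. Generated data is")
print("cleanly separated by construction, so both models score highly.")
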