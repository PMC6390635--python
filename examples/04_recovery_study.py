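"""Monte-Carlo parameter recovery under realistic acquisition noise.

Repeats phantom -> subtraction -> calibration -> extraction -> fit with
independent 5% Rician noise and summarises bias, RMSE and coverage.
(Small replicate count for a quick demo; increase n_reps for smooth
statistics.)
"""

from issdiff import default_truth, recovery_experiment, summarize_recovery

truth = default_truth(seed=0)
table = recovery_experiment(truth, n_reps=8, seed=0)
summary = summarize_recovery(table)
print(summary.to_string(index=False))
print("\nDiffusivities recover to a few percent; the clearance rate k is "
      "weakly identified at this noise level (its decay signature over six "
      "hours is ~25%, below the per-frame noise) and tends to its bound.")
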