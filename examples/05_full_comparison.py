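"""The full efficiency-matched comparison of LSCAT, SC and DTCAT.

The cross-factorial post-hoc simulation: split the data 50/50, calibrate
every method on one half, match SC's and DTCAT's average test length to
LSCAT's (tuned a priori, on calibration data only), administer on the
other half, and compare predictive validity.
"""

from lscat import ExperimentConfig, generate, run_experiment
from lscat.synthdata import phq9_preset

data, _ = generate(phq9_preset(10_000, seed=5))
config = ExperimentConfig(cutoffs=(5, 10), criteria=(0.95, 0.99),
                          n_classes=3, n_starts=5, seed=5)
result = run_experiment(data, config)

print("Efficiency (matched average administered items):")
cols = ["cutoff", "stopping_criterion", "method", "mean_items", "sd_items",
        "min_items", "max_items"]
print(result.efficiency_table[cols].round(3).to_string(index=False))

print("\nPredictive validity on the validation half:")
cols = ["cutoff", "stopping_criterion", "method", "type_i_error",
        "type_ii_error", "accuracy", "kappa"]
print(result.validity_table[cols].round(3).to_string(index=False))

print("\nEach validity row compares predicted with true (complete-data) "
      "status.  The base-rate rows are the random-assignment floor (kappa "
      "~ 0); the adaptive methods sit near-perfect, with the latent-class "
      "engine typically lowest on Type I error and highest on accuracy.")
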