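"""Calibrate the latent class engine: EM estimation with BIC model selection.

The engine behind adaptive screening is an unrestricted latent class
model.  We fit K = 1..4 classes to synthetic calibration data and let BIC
choose K; with data generated from a 3-class model, BIC should land on 3.
"""

from lscat import generate, select_n_classes
from lscat.synthdata import phq9_preset

data, _ = generate(phq9_preset(5_000, seed=2))
params, table = select_n_classes(data, max_classes=4, n_starts=5, seed=0)

print(table[["n_classes", "log_likelihood", "n_params", "bic"]].round(1).to_string(index=False))
print(f"\nBIC selects K = {params.n_classes} classes")
print("class weights:", params.class_weights.round(3))
print("\nEach row above is one candidate model; BIC = -2 logL + p ln N "
      "penalizes the extra parameters of larger K.  The class weights are "
      "the mixing proportions of the selected engine.")
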