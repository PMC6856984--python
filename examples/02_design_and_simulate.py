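"""Sobol designs and the toy left-ventricle simulator.

Builds a space-filling training design over the parameter box [0.1, 5]^4,
pushes it through the deterministic toy simulator (24 segment strains + LV
volume per parameter vector) and writes the paired dataset to CSV.
"""

import numpy as np

import lvemulate as lv
from lvemulate.design import DesignSpec

train, test = lv.generate_dataset(n_train=128, n_test=4)

print(f"training design: {train.design.shape}, outputs: {train.outputs.shape}")
print(f"test     design: {test.design.shape}, outputs: {test.outputs.shape}")

theta = train.design[0]
y = train.outputs[0]
print(f"\nfirst design point theta = {np.round(theta, 3).tolist()}")
print(f"  strains (first 6): {np.round(y[:6], 4).tolist()}")
print(f"  end-diastolic volume: {y[-1]:.2f} mL")

stiff = lv.simulate_output([5, 5, 5, 5])
soft = lv.simulate_output([0.1, 0.1, 0.1, 0.1])
print(
    f"\nstiffest corner volume {stiff[-1]:.1f} mL < softest corner volume "
    f"{soft[-1]:.1f} mL: stiffer tissue admits less filling."
)

print("\n(write_dataset/read_dataset round-trip CSVs with columns theta1..4, strain01..24, volume)")
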