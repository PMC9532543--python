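"""Validate the source model against a classic water-hammer experiment.

A 0.67 kg steel projectile at 18.5 m/s strikes a water-filled specimen
tube (38.1 mm bore, closed far end).  The impedance-matched source model
predicts the impacted-end peak pressure; the closed-end solve shows the
reflected wave the experiment records.
"""

import numpy as np

from cellhammer import preset_config, run_simulation, run_validation_shot62

summary = run_validation_shot62()
print(f"predicted peak pressure : {summary['predicted_peak_MPa']:.2f} MPa")
print(f"published computation   : {summary['reference_numerical_peak_MPa']:.2f} MPa "
      f"({100*summary['rel_err_vs_numerical']:+.1f}%)")
print(f"published measurement   : {summary['reference_experimental_peak_MPa']:.2f} MPa "
      f"({100*summary['rel_err_vs_experimental']:+.1f}%)")
print(f"Joukowsky rigid bound   : {summary['joukowsky_bound_MPa']:.2f} MPa "
      "(prediction must stay below)")

res = run_simulation(preset_config("shot62"))
field = res.field
end_peak = (field.p[:, -1].max() - field.ambient) / 1e6
inlet_peak = (field.p[:, 0].max() - field.ambient) / 1e6
print(f"closed-end peak         : {end_peak:.2f} MPa "
      f"(~2x the incident {inlet_peak:.2f} MPa: dead-end doubling)")
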