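"""Check a channel design: celerity, rigidity, continuum and grid criteria.

For the water-filled 3x3x60 mm glass channel the wave celerity is within
a few percent of the free-water sound speed, the fluid-loading number is
far below 1 (walls effectively rigid) and the Knudsen number is far
below the continuum threshold.
"""

from cellhammer import preset_config, run_design

report = run_design(preset_config("representative"))

ac = report.acoustics
print(f"wave celerity cf      : {ac['cf']:.1f} m/s "
      f"({100*(1 - ac['cf']/1439):.1f}% below c0)")
print(f"corrected bulk modulus: {ac['Kmod']/1e9:.3f} GPa")
print(f"fluid loading beta    : {ac['beta']:.3e}  (rigid if << 1)")
print(f"Knudsen number        : {ac['Kn']:.1e}   (continuum if < 1e-3)")
print(f"grid                  : dz={report.grid['dz']*1e3:.2f} mm, "
      f"dt={report.grid['dt']*1e9:.1f} ns, Courant={report.grid['courant']:.3f}")
print(f"criteria              : {report.criteria}")
print(f"weak-shock front-speed correction: "
      f"{100*report.weak_shock['front_speed_correction_frac']:.2f}% "
      "(reported, not fed back into propagation)")
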