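"""Build the impact pressure pulse for a PMMA projectile.

Impedance matching between projectile and water sets the amplitude;
Newton's law for the decelerating projectile sets the exponential decay.
"""

from cellhammer import PMMA, WATER, ProjectileSpec, matched_amplitude, pulse
from cellhammer.source import integrate_projectile_ode

proj = ProjectileSpec(material=PMMA, length=0.01, area=9e-6, up=3.0)
src = pulse(WATER, proj)

print(f"projectile: 1 cm PMMA slug at {proj.up} m/s, mass {proj.mass*1e3:.2f} g")
print(f"pulse amplitude p(0)     : {src.p_peak/1e6:.3f} MPa (gauge)")
print(f"decay constant lambda    : {src.lam:.4g} 1/s  (1/e time {src.decay_time*1e6:.2f} us)")

# independent check: step-by-step integration of the projectile motion
t, p = integrate_projectile_ode(WATER, proj, 5 * src.decay_time, src.decay_time / 400)
import numpy as np

err = np.max(np.abs(p / p[0] - np.exp(-src.lam * t)))
print(f"ODE oracle vs closed form: max profile deviation {err:.2e}")

# controllability: amplitude follows velocity, duration follows length
for up in (1.0, 2.0, 4.0):
    print(f"  up = {up} m/s -> p(0) = "
          f"{matched_amplitude(WATER, ProjectileSpec(PMMA, 0.01, 9e-6, up))/1e6:.2f} MPa")

# The amplitude is ~1 MPa per m/s of impact velocity and the decay time
# is proportional to projectile length: both knobs are independent.
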