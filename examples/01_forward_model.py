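"""Closed-form forward model: where does a bolus go, and how fast is it cleared?

Evaluates the anisotropic point-source solution at a few positions and
times, checks total dissolved mass, and prints the derived scalar metrics.
"""

import numpy as np

from issdiff import (
    DiffusionParameters,
    InstantaneousSource,
    average_diffusion,
    concentration_instantaneous,
    half_life,
    tortuosity,
    total_dissolved_mass,
)

# tissue-order parameters: effective diffusivities ~1e-4 mm^2/s, clearance
# 1.4e-5 /s, interstitial volume fraction 20%
params = DiffusionParameters(d_x=1.0e-4, d_y=1.5e-4, d_z=0.8e-4,
                             k=1.4e-5, alpha=0.2)
bolus = InstantaneousSource(mass=20.0)  # 2 ul of a 10 mM infusate, nmol

print("Concentration (mM) at 1 mm from the source along each axis:")
for t_min in (10, 60, 180, 360):
    t = 60.0 * t_min
    pts = np.array([[1.0, 0, 0, t], [0, 1.0, 0, t], [0, 0, 1.0, t]])
    cx, cy, cz = concentration_instantaneous(params, bolus, pts)
    print(f"  t = {t_min:3d} min:  x: {cx:7.3f}   y: {cy:7.3f}   z: {cz:7.3f}")

print("\nTotal dissolved mass (M/alpha) e^{-kt}, nmol:")
for t_min in (10, 180, 360):
    m = total_dissolved_mass(params, bolus, 60.0 * t_min)
    print(f"  t = {t_min:3d} min:  {m:8.3f}")

print("\nDerived metrics:")
print(f"  average D (rss)  = {average_diffusion(params, 'rss'):.3e} mm^2/s")
print(f"  average D (rms)  = {average_diffusion(params, 'rms'):.3e} mm^2/s")
print(f"  half-life        = {half_life(params.k):.0f} s "
      f"({half_life(params.k) / 3600:.1f} h)")
# tortuosity vs free-solution diffusivity of a small Gd chelate
print(f"  tortuosity       = {tortuosity(3.8e-4, average_diffusion(params, 'rms')):.2f} "
      "(vs D_free = 3.8e-4 mm^2/s)")
print("\nDiffusion is fastest along y (largest D), clearance halves the "
      "dissolved tracer in ~14 h.")
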