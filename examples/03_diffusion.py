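"""Lateral lipid diffusion from time-averaged MSD with drift correction.

A Brownian membrane is generated with a known diffusion constant of
2 um^2/s and deliberate, opposing per-leaflet drift. Unwrapping plus
whole-membrane and per-leaflet center-of-mass correction removes the
drift, and the Einstein fit recovers the input D.
"""

import oxmem
from oxmem.dynamics import (diffusion_coefficient, msd_lateral,
                            unwrap_and_correct)
from oxmem.synthetic import gen_brownian_membrane

native = oxmem.build_native_composition()
D_true = 2.0  # um^2/s
traj, _ = gen_brownian_membrane(
    native, {name: D_true for name in native.species_counts()},
    n_frames=4000, dt=100.0,
    leaflet_drift={"inner": (1e-3, 0.0), "outer": (-1e-3, 5e-4)},
    seed=0)

tracks = unwrap_and_correct(traj)
msd = msd_lateral(tracks)[("all", "all")]
est = diffusion_coefficient(msd)
print(f"input D      = {D_true} um^2/s (plus opposing leaflet drift)")
print(f"recovered D  = {est.D:.3f} um^2/s")
print(f"fit window   = {est.fit_window[0]:.0f}-{est.fit_window[1]:.0f} ps, "
      f"R^2 = {est.r_squared:.4f}")
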