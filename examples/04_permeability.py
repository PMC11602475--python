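"""Water-permeation pipeline: umbrella sampling -> WHAM -> D(z) -> P.

Exact Boltzmann samples are drawn from a two-well membrane PMF (26 kJ/mol
central barrier, 5 kJ/mol interfacial wells) over the standard pull
schedule of 40 windows, 0.2 nm apart, k = 100 kJ/mol/nm^2, pulled from
z = +4 to -4 nm. WHAM reconstructs the profile, force autocorrelation
gives the local diffusivity, and the inhomogeneous solubility-diffusion
integral yields the permeability.
"""

import numpy as np

import oxmem
from oxmem.pmf import make_window_schedule, permeability, wham
from oxmem.synthetic import gen_force_series, gen_umbrella_samples
from oxmem.units import NM_PS_TO_CM_S, R_KJ, kT as kT_of

T = 298.0
kT = kT_of(T)


def two_well(z):
    z = np.asarray(z, float)
    return (26.0 * np.exp(-z ** 2 / (2 * 0.8 ** 2))
            - 5.0 * np.exp(-(z - 2.2) ** 2 / (2 * 0.35 ** 2))
            - 5.0 * np.exp(-(z + 2.2) ** 2 / (2 * 0.35 ** 2)))


sched = make_window_schedule(4.0, -4.0, 0.2, 100.0)
# P depends exponentially on the barrier, so a 0.5 kJ/mol WHAM error is a
# ~20% permeability error; sample generously
windows, _ = gen_umbrella_samples(two_well, sched.centers,
                                  sched.force_constant, 400_000, kT, seed=0)
pmf = wham(windows, kT)
print(f"windows            : {len(windows)} "
      f"(centers {sched.centers[0]:+.1f} to {sched.centers[-1]:+.1f} nm)")
print(f"barrier over bulk  : {pmf.barrier_height('bulk'):.2f} kJ/mol "
      "(truth 26)")

D_true = 5e-4  # nm^2/ps
forces, _ = gen_force_series(D_true, T, tau=1.0, n=40_000, dt=0.2, seed=1,
                             centers=sched.centers)
dprof = oxmem.diffusion_from_force_autocorrelation(forces, T)
print(f"mean D(z)          : {dprof.D.mean():.2e} nm^2/ps "
      f"(truth {D_true:.0e})")

bounds = (float(sched.centers.min()), float(sched.centers.max()))
res = permeability(pmf, dprof, T=T, bounds=bounds)

# direct quadrature of the known PMF over the same span, for reference
RT = R_KJ * T
z = np.linspace(bounds[0], bounds[1], 40_001)
G = two_well(z)
G -= two_well(np.linspace(bounds[1] - 0.5, bounds[1], 200)).mean()
P_ref = 1.0 / np.trapezoid(np.exp(G / RT) / D_true, z) * NM_PS_TO_CM_S

print(f"permeability       : {res.P:.3e} cm/s")
print(f"direct quadrature  : {P_ref:.3e} cm/s "
      f"({100 * abs(res.P - P_ref) / P_ref:.1f}% apart)")
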