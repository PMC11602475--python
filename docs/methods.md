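# Methods

This document states the definitions, conventions, and numerical methods
implemented by `oxmem`. Units throughout: length nm, time ps, mass amu,
energy kJ/mol. Temperature defaults to 298 K, where
kT = 2.477 kJ/mol and RT = 2.477 kJ/mol. Conversions: 1 nm²/ps =
10⁶ µm²/s; 1 nm/ps = 10⁵ cm/s.

## Membrane composition model

The native red-blood-cell membrane patch is a fixed asymmetric table of
34 lipid species: 200 phospholipids (157 in the inner leaflet, 143 in
the outer, counting cholesterol in neither) plus 100 cholesterol split
50/50 between leaflets, i.e. a cholesterol:phospholipid molar ratio of
0.5. Phosphatidylserine carries charge −1e, giving a net membrane charge
of −24e.

The ferroptosis (oxidized) variant is produced by `apply_ferroptosis_
substitution`: every phospholipid carrying a polyunsaturated fatty acid
(PUFA) chain — linoleic (LA, 18:2), arachidonic (AA, 20:4), or
docosahexaenoic (DHA, 22:6) — is replaced by its hydroperoxide (HPD)
isomers:

- single sn-2 PUFA chains split 50/50 between the two positional
  isomers (9-/13-HPODE for LA, 12-/15-HPETE for AA, 14-/17-HPDHE for
  DHA); odd copy counts are resolved by a rounding policy
  (`half_up`, `half_down`, or seeded `random`);
- di-PUFA species map to the fixed sn1/sn2 isomer pair (13/9, 15/12,
  17/14).

Each HPD isomer keeps the carbon count and double-bond count of its
parent chain, with one bond shifted to the trans configuration adjacent
to the -OOH carbon. The substitution conserves per-leaflet lipid counts,
total lipid count, and net charge exactly.

## Trajectory I/O

GRO/PDB single frames and XTC/DCD trajectories are read and written via
MDAnalysis; coordinates are converted to nm (PDB Å are divided by 10).
Umbrella window time series use two-column text files (time, position;
`#`/`@` comment lines skipped) with a JSON sidecar providing window
center and force constant. Malformed records raise errors naming file
and line.

## Synthetic generators

All analysis stages are validated against generators with closed-form
truth:

- **Brownian membrane** — per-lipid 2-D Gaussian walks with per-step
  variance 2·D·dt per axis plus shared per-leaflet drift; z fixed per
  leaflet.
- **Ordered chains** — all-trans carbon skeletons at a prescribed tilt t
  from the membrane normal (or isotropic orientations), with an optional
  gauche-kink fraction. With zero gauche fraction every internal
  skeletal vector makes angle t with z, so S_CD = (3cos²t − 1)/2
  exactly.
- **Layered bilayer** — component z-coordinates from leaflet-mirrored
  Gaussians; waters uniform outside an exclusion slab.
- **Umbrella samples** — rejection-free inverse-CDF samples from the
  exact biased density ∝ exp(−[G(z) + k/2 (z−z_i)²]/kT) on a fine grid;
  the exact density per window is retained for oracle comparisons.
- **Force series** — stationary Ornstein–Uhlenbeck processes with
  autocovariance σ² e^(−t/τ) and σ²τ = (RT)²/D, matching the
  force-autocorrelation diffusivity estimator.
- **H-bond fixtures** — exactly k triplets satisfying the geometric
  criteria and k' violating them by stated distance/angle margins.

## Structural analyses

**Mass density profiles.** Per-frame histograms of mass/(bin volume)
along z, recentered on the membrane center of mass and averaged over
frames (bin width 0.05 nm by default).

**Thickness.** Peak position per leaflet by parabolic interpolation of
the 3-point-smoothed histogram maximum in each half-space; thickness is
the peak-to-peak distance. The peak-shift diagnostic reports the signed
per-leaflet displacement of one profile's peaks relative to another
(positive = toward the membrane center).

**Area per lipid.** box_x·box_y / N_leaflet per frame, counting
phospholipids only or phospholipids + cholesterol by flag.

**Deuterium order parameter.** S_CD(j) = ⟨(3cos²θ_j − 1)/2⟩ where θ_j is
the angle between the skeletal vector C(j−1)→C(j+1) and the membrane
normal, averaged over frames and chain copies; terminal carbons are
excluded. Chain-averaged and per-fatty-acid pooled summaries are
derived from the per-carbon table.

**Tail angles.** From per-lipid marker atoms: α (P→terminal-CH3 vs the
outward-to-inward leaflet normal), β (angle between the two chain
vectors), γ (interior angle at a pivot carbon), δ (P→carbonyl segment vs
normal), and the cholesterol ring-axis tilt α3.

## Hydrogen bonds

A bond is a donor–H/acceptor pair with D–A distance ≤ 0.35 nm and
H–D⋯A angle ≤ 30°, using minimum-image distances. Candidate pairs come
from a cKDTree over a periodic-image-augmented acceptor set; the
detector is validated against an O(N²) brute-force reference.
Contact-rate summaries average per-frame bond counts per group
instance, keyed by (group, leaflet, partner class).

## Lateral diffusion

Per-lipid xy center-of-mass tracks are PBC-unwrapped, then corrected by
removing whole-membrane and per-leaflet COM displacement (in that
order), which cancels imposed or spurious drift. The time-averaged MSD
is computed per (species, leaflet) group with an FFT-based estimator
(identical to the naive O(N²) sum to ≤1e-10 relative error). The
diffusion coefficient is the least-squares MSD slope over a fit window
(default 10–50% of the maximum lag, which defaults to one fifth of the
trajectory) divided by 4, reported in µm²/s with per-lipid spread.

## PMF, diffusivity profile, and permeability

**Window schedule.** Default: pull from z = +4.0 to −4.0 nm in 0.2 nm
steps with k = 100 kJ/mol/nm², a half-open count convention giving 40
windows with centers +4.0 … −3.8 nm. The leading fraction of each
window (default one half) is discarded as equilibration.

**WHAM.** Self-consistent iteration in log space (log-sum-exp):
p(z) ∝ Σᵢ nᵢ(z) / Σᵢ Nᵢ fᵢ⁻¹ exp(−Uᵢ(z)/kT), fᵢ⁻¹ = Σ_z p(z)
exp(−Uᵢ(z)/kT), iterated until the maximum change in the window free
energies is below tolerance (error on non-convergence). ΔG(z) =
−kT ln p(z), anchored to zero at the bulk-water plateau on the side
where the pull started. Non-overlapping windows raise an error
identifying the gap. The dominant statistical error is a random walk of
the per-window free energies across the schedule; bins beyond the
window-center span are sparsely sampled and carry large uncertainty.

**Diffusivity profile.** D(zᵢ) = (RT)² / ∫₀^∞ ⟨δF(t)δF(0)⟩ dt per
window, with the autocorrelation integral truncated at its first zero
crossing (default) or by an exponential tail fit. Series whose
correlation time is not resolved by the sampling interval are rejected
as white noise.

**Permeability.** Inhomogeneous solubility-diffusion:
P = [∫ exp(ΔG(z)/RT) / D(z) dz]⁻¹ by trapezoidal quadrature over a
common grid, converted to cm/s. Closed-form checks: a flat profile
gives P = D/L exactly; a square barrier of height G and width w gives
P = D/[(L−w) + w·e^{G/RT}]. Because P depends exponentially on the
barrier, a 0.5 kJ/mol PMF error translates to roughly 20% in P.

## Orchestration

`RunConfig` validates YAML configs (unknown keys rejected before any
work), and `run_pipeline` executes recipe stages in dependency order.
Every artifact is written with a JSON sidecar carrying the config hash
and seed; deterministic stages reproduce byte-identical outputs under
identical configs. The `oxmem` CLI is a thin layer over the library:
exit code 0 on success, 2 on validation errors, 3 on runtime failures.
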