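"""Build the native RBC membrane model and its ferroptosis-oxidized
counterpart, then report the lipid bookkeeping.

The native composition is an asymmetric 300-lipid bilayer (200
phospholipids + 100 cholesterol). Oxidation replaces a fraction of the
polyunsaturated chains with their hydroperoxide (HPD) isomers while
conserving every per-leaflet count and the total charge.
"""

import oxmem

native = oxmem.build_native_composition()
print("native membrane")
print(f"  phospholipids : {native.total_phospholipids}")
print(f"  cholesterol   : {native.total_cholesterol}")
print(f"  chol:PL ratio : "
      f"{native.total_cholesterol / native.total_phospholipids}")
print(f"  inner leaflet : {native.leaflet_total('inner')} lipids")
print(f"  outer leaflet : {native.leaflet_total('outer')} lipids")
print(f"  net charge    : {native.total_charge} e")

ferro = oxmem.apply_ferroptosis_substitution(native, seed=0)
print("\nhydroperoxide content after substitution (mol% of phospholipids)")
for key, pct in sorted(oxmem.hpd_mole_percent(ferro).items()):
    print(f"  {key:<18s} {pct:5.2f}")

assert ferro.total_lipids == native.total_lipids
assert ferro.total_charge == native.total_charge
print("\ncounts and charge conserved by the substitution")
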