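"""Carbonate speciation at measured pH, and the pH<->DIC inverse pair.

Builds the artificial-seawater medium used for the incubations, speciates
DIC at a typical incubation pH, and shows that pH and DIC determine each
other at fixed total alkalinity — the fact the whole pH-oscillation method
rests on.
"""

from phoskit import MediumChemistry, dic_from_ph, equilibrium_constants, ph_from_dic, tris_ph

chem = MediumChemistry(
    salinity=35.0, temperature=298.15, total_alkalinity=1980.1,
    density=1.0352, total_phosphate=21.8, total_silicate=105.6,
)
k = equilibrium_constants(chem)

s = dic_from_ph(8.05, chem, k)
print(f"at pH_T 8.05, A_T {chem.total_alkalinity} umol/kg:")
print(f"  CO2  = {s.CO2:8.2f} umol/kg   (dissolved gas, ~0.5% of the pool)")
print(f"  HCO3 = {s.HCO3:8.2f} umol/kg   (dominant species)")
print(f"  CO3  = {s.CO3:8.2f} umol/kg")
print(f"  DIC  = {s.DIC:8.2f} umol/kg   A_c = {s.A_c:.2f} umol/kg")

# the inverse solve: what pH corresponds to 10 umol/kg of carbon uptake?
ph2 = ph_from_dic(s.DIC - 10.0, chem, k)
print(f"removing 10 umol/kg DIC raises pH from 8.0500 to {ph2:.4f}")
print(f"(so ~{10/(ph2-8.05):.0f} umol/kg DIC per pH unit at this point)")

# the Tris buffer reference that anchors the NBS -> total scale conversion
print(f"Tris-ASW reference pH at S=35, 25 C: {tris_ph(35.0, 298.15):.4f}")
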