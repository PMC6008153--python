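"""Quantum yields of carbon uptake and oxygen evolution vs irradiance.

Divides the fitted net photosynthetic rate by the absorbed photon flux
(the spectral integral of the chlorophyll-specific absorption coefficient
times the lamp spectrum) and locates the peak of the Phi-vs-E curve. Because
net rates carry the respiration load, the maximum yield sits at intermediate
light, not in the low-light limit.
"""

from phoskit import (
    MediumChemistry, SimulationConfig, fit_platt_offset, phi_series,
    pve_points, simulate_spectrum, simulate_trace, specific_absorption,
    white_led_spectrum,
)

chem = MediumChemistry(35.0, 298.15, 1980.1, total_phosphate=21.8,
                       total_silicate=105.6)
cfg = SimulationConfig(chemistry=chem, chla=2.0, pq=1.2, sigma_ph=5e-4, seed=9)
trace = simulate_trace(cfg)
points = pve_points(trace, o2_cal=cfg.oxygen_calibration(), schedule=cfg.schedule)
fits = {
    "carbon": fit_platt_offset(points, gas="carbon"),
    "oxygen": fit_platt_offset(points, gas="oxygen", rate_attr="rate_O2"),
}

# whole-cell absorbance -> chlorophyll-specific absorption a*_ph(lambda)
absorbance, _ = simulate_spectrum(chla_mg_m3=cfg.chla * 1000.0, seed=9)
a_star = specific_absorption(absorbance, chla_mg_m3=cfg.chla * 1000.0, path_m=0.01)

ps = phi_series(fits, a_star, white_led_spectrum())
for gas in ("carbon", "oxygen"):
    print(f"Phi_max({gas}) = {ps.phi_max[gas]:.4f} mol/mol quanta "
          f"at E = {ps.E_at_phi_max[gas]:.0f} umol quanta m-2 s-1")
print(f"PQ at P_max = {ps.PQ_at_Pmax:.3f} (O2 evolved per C fixed)")
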