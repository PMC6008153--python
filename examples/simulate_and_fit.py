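"""Forward-simulate one pHOS-MIMS incubation and recover its P-vs-E truth.

A known photosynthesis-irradiance curve drives the simulated pH and O2/Ar
channels; the pipeline then works backwards from the channels to
chlorophyll-specific rates and the fitted parameters. Agreement between the
fitted and generating parameters is the package's core self-consistency
check.
"""

from phoskit import MediumChemistry, SimulationConfig, fit_platt_offset, pve_points, simulate_trace

chem = MediumChemistry(
    salinity=35.0, temperature=298.15, total_alkalinity=1980.1,
    total_phosphate=21.8, total_silicate=105.6,
)
cfg = SimulationConfig(
    chemistry=chem, p_max=154.79, alpha=1.11, beta=0.0, respiration=10.0,
    pq=1.2, chla=2.0, sigma_ph=5e-4, seed=42,
)
trace = simulate_trace(cfg)
print(f"simulated {len(trace)} s of 1 Hz data, pH span "
      f"{trace.ph.min():.4f}..{trace.ph.max():.4f}")

points = pve_points(trace, o2_cal=cfg.oxygen_calibration(), schedule=cfg.schedule)
print("\nlight  rate_C (umol C/mg Chla/h)  rate_O2")
for p in points:
    print(f"{p.light_level:5.0f}  {p.rate_DIC:10.2f}  {p.rate_O2:22.2f}")

fit_c = fit_platt_offset(points, gas="carbon")
fit_o = fit_platt_offset(points, gas="oxygen", rate_attr="rate_O2")
print(f"\ncarbon fit:  P_max={fit_c.P_max:.2f} (truth {cfg.p_max}), "
      f"alpha={fit_c.alpha:.3f} (truth {cfg.alpha}), R={fit_c.respiration_offset:.2f}")
print(f"oxygen fit:  P_max={fit_o.P_max:.2f}")
print(f"photosynthetic quotient P_max(O2)/P_max(C) = "
      f"{fit_o.P_max / fit_c.P_max:.3f} (truth {cfg.pq})")
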