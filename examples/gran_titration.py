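"""Total alkalinity by Gran titration of a simulated sample.

Alkalinity is the one carbonate-system input the pH-oscillation method needs
from the wet lab; the Gran reduction linearizes the acid-excess region of a
titration and reads A_T off the equivalence point.
"""

from phoskit import gran_alkalinity, simulate_titration

true_at = 1980.1  # umol/kg, the measured medium alkalinity
rec = simulate_titration(true_at, sample_mass=50.0, acid_conc=0.1723,
                         noise_ph=0.002, seed=1)
res = gran_alkalinity(rec)
print(f"titration: {len(rec.points)} additions of {rec.acid_concentration} "
      f"mol/kg HCl into {rec.sample_mass} g of sample")
print(f"Gran line r^2 = {res.r2:.6f} over {res.n_points} acid-excess points")
print(f"recovered A_T = {res.A_T:.1f} umol/kg "
      f"(truth {true_at}; error {100 * (res.A_T / true_at - 1):+.3f}%)")
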