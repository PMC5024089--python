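"""Fit the ink physics models on synthetic characterization data.

Generates noise-free curves at the documented material parameters and shows
that each fit reads the generating value back: the Ostwald flow indices of
the AS3 support ink (n = 0.3) and the cell-laden A-NIH bio-ink (n = 0.26),
the 35 degC gel point of AS3, and the 500.4 kPa center-square modulus. Ends
with the reservoir-temperature window for the bio-ink pair and a lumped
cooling estimate for a 3 s ink switch.
"""

from aspireprint.fixtures import (
    gen_gelation_curve, gen_powerlaw_curve, gen_stress_strain, table_inks,
)
from aspireprint.inks import (
    InkSpec, find_crossover, fit_modulus, fit_power_law, gelation_risk,
    printability_window, switching_temperature_drop,
)

for ink, n_true in (("AS3", 0.30), ("A-NIH", 0.26)):
    g, eta = gen_powerlaw_curve(K=100.0, n=n_true, shear_range=(0.01, 100.0))
    fit = fit_power_law(g, eta)
    print(f"{ink}: fitted n = {fit.n:.4f} (generated with {n_true}), "
          f"K = {fit.K:.1f} Pa*s^n -> shear thinning: {fit.shear_thinning}")

curve = gen_gelation_curve(T_x=35.0, T_range=(20.0, 50.0), step=0.5)
print(f"AS3 gel point from G'-G'' crossover: {find_crossover(curve):.2f} degC")

ss = gen_stress_strain(E=500.4, max_strain=0.15)
print(f"center-square modulus from 0-4% window: {fit_modulus(ss):.1f} kPa")

bio = [table_inks()["AS3"], InkSpec("A-NIH", crossover_T=35.0)]
lo, hi = printability_window(bio, margin=3.0, ceiling=38.0)
print(f"bio-ink reservoir window: [{lo:g}, {hi:g}] degC "
      "(38 degC keeps inks liquid without cooking cells)")

T = switching_temperature_drop(T0=50.0, T_env=25.0, elapsed=3.0, tau=30.0)
risky = gelation_risk(T, [i for i in table_inks().values() if i.crossover_T])
print(f"column temperature after a 3 s switch from 50 degC: {T:.2f} degC; "
      f"inks at gelation risk: {[i.ink_id for i in risky] or 'none'}")
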