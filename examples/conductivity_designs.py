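"""Series-circuit conductivity of the three segmented filament designs.

24 mm filaments of AC3 (more conductive) with an AC1 middle segment of 4, 8
or 12 mm: each segment acts as a resistor in series, so the effective
specific conductivity is the length-weighted harmonic mean and falls as the
less-conductive middle grows. Segment conductivities here are synthetic
stand-ins on the documented geometry. Also closes the loop through a
simulated resistance measurement (sigma = L / (R A)).
"""

from aspireprint.fixtures import gen_three_segment_filament
from aspireprint.inks import (
    ConductivitySegmentSpec,
    resistance_from_conductivity,
    series_conductivity,
    specific_conductivity_from_resistance,
)

SIGMA = {"AC3": 3.0, "AC1": 1.0}  # synthetic S/m for the two inks

for design, middle in enumerate((4.0, 8.0, 12.0), start=1):
    fil = gen_three_segment_filament(24.0, middle, ("AC3", "AC1"))
    segs = [ConductivitySegmentSpec(s.ink_id, s.length, SIGMA[s.ink_id])
            for s in fil.segments]
    eff = series_conductivity(segs)
    lengths = "/".join(f"{s.length:g}" for s in fil.segments)
    R = resistance_from_conductivity(eff, 24.0, 0.5)
    back = specific_conductivity_from_resistance(R, 24.0, 0.5)
    print(f"design {design}: AC3-AC1-AC3 = {lengths} mm -> "
          f"sigma_eff = {eff:.4f} S/m (R = {R/1e6:.2f} Mohm, "
          f"back-computed {back:.4f} S/m)")

print("\nlonger AC1 middle -> lower overall conductivity, bounded by the "
      "segment conductivities (1.0 and 3.0 S/m).")
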