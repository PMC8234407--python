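"""Evaluate the flexible-biosensor design formulas at the fabricated
geometry: a 60 × 25 mm², 0.3 mm PDMS/hydrogel film with E = 286 kPa.
"""

from eogkit import (SensorGeometry, cantilever_constant,
                    load_deflection_pressure, resistivity, youngs_modulus)

film = SensorGeometry(width=0.025, thickness=3e-4, length=0.06,
                      youngs_modulus=286e3, poisson_ratio=0.3)

k = cantilever_constant(film)
print(f"cantilever elastic constant K = {k:.3e} N/m")

p = load_deflection_pressure(film, deflection=1e-3)
print(f"pressure at 1 mm deflection   P = {p:.3f} Pa")

e = youngs_modulus(force=0.07, length=1.0, area=0.025 * 0.5e-3, elongation=0.2)
print(f"modulus from 0.07 N at 20% strain (25 x 0.5 mm^2 section): {e / 1e3:.0f} kPa")

out = resistivity(voltage=2.0, current=1e-3, cross_section=5e-6, length=0.01)
print(f"voltammetric resistivity rho = {out['resistivity_ohm_m']:.2f} ohm.m, "
      f"conductivity = {out['conductivity_S_per_m']:.2f} S/m")

print("\nA soft (hundreds of kPa), compliant film keeps K small so the "
      "sensor follows skin deformation instead of resisting it.")
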