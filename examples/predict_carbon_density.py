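"""Predict bulk density and carbon density from a carbon fraction alone.

A sediment sample whose dry mass is 20% organic carbon is, at a conversion
factor f = 2.2, about 44% organic matter; the mixing model turns that into
a bulk density and hence a carbon density without ever weighing a known
volume of sediment.
"""

from sedcarbon import (
    MixingParams,
    bulk_density_from_carbon,
    carbon_density_gravimetric,
    carbon_density_mixing,
    organic_from_carbon,
)

params = MixingParams(delta_p=0.09, delta_m=1.75, f=2.2)

for c in (0.02, 0.10, 0.20, 0.40):
    o = organic_from_carbon(c, params)
    delta = bulk_density_from_carbon(c, params)
    d = carbon_density_mixing(c, params)
    print(
        f"C = {c:4.2f}  ->  organic matter {100 * o:5.1f} %, "
        f"bulk density {delta:.3f} g/cm^3, carbon density {d:.4f} g C/cm^3"
    )

# the same carbon density from a measured (gravimetric) bulk density
print(
    "\ngravimetric check at C = 0.20, measured delta = 0.24 g/cm^3:",
    f"{carbon_density_gravimetric(0.20, 0.24):.4f} g C/cm^3",
)
print(
    "Carbon-poor (mineral) sediment is dense; carbon-rich (peaty) sediment is light.\n"
    "Because the two effects offset, carbon density rises only gently with C."
)
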