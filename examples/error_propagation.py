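"""Why multiplying two noisy measurements is costly — and when it isn't.

The gravimetric carbon density D = C * delta multiplies two measured
quantities, so its variance follows the independent-product formula
V(xy) = E(y)^2 V(x) + E(x)^2 V(y) + V(x)V(y): absolute error grows with
the sediment's carbon content.  The mixing-model estimator D = g(C) uses
only the carbon fraction; its delta-method variance g'(C)^2 V(C) shrinks
in peaty sediment because the slope g'(C) = delta_C^2 / delta_m collapses.
"""

import numpy as np

from sedcarbon import (
    MixingParams,
    bulk_density_from_carbon,
    mixing_estimator_variance,
    product_variance,
)

params = MixingParams(0.09, 1.75, 2.2)
cv = 0.10  # 10% relative measurement error on both C and delta

print(f"{'C':>5} {'delta':>7} {'SD gravimetric':>15} {'SD mixing':>10} {'ratio':>7}")
for c in (0.02, 0.05, 0.10, 0.20, 0.30, 0.40):
    delta = bulk_density_from_carbon(c, params)
    var_grav = product_variance(c, (cv * c) ** 2, delta, (cv * delta) ** 2)
    var_mix = mixing_estimator_variance(c, (cv * c) ** 2, params)
    ratio = np.sqrt(var_grav / var_mix)
    print(f"{c:5.2f} {delta:7.3f} {np.sqrt(var_grav):15.5f} "
          f"{np.sqrt(var_mix):10.5f} {ratio:7.1f}")

print(
    "\nSD in g C/cm^3. The product estimator's error grows ~proportionally to\n"
    "carbon density, while the carbon-fraction-only estimator becomes MORE\n"
    "precise as sediment gets peatier: in organic-rich sediment the mixing\n"
    "route is an order of magnitude tighter (given accurate parameters)."
)
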