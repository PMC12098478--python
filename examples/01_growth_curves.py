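"""Evaluate the three tumour-growth laws at a few clinically relevant times.

Volumes are mm^3, times months since detection (a 0.5 mm sphere,
0.065 mm^3).  Exponential growth is unbounded, Gompertz saturates at the
carrying capacity K, and the Gyllenberg-Webb compartment model produces an
S-shaped curve from the balance of proliferating and quiescent cells.
"""

import numpy as np

from oncotraj import ExponentialGrowth, GompertzGrowth, GyllenbergWebbGrowth

exp_g = ExponentialGrowth(S0=0.065, beta=0.5)
gom_g = GompertzGrowth(S0=0.065, beta=0.2, K=150_000.0)  # K = 150 cm^3
gw_g = GyllenbergWebbGrowth(b=1.0, mu_q=0.05, d_clear=0.01, P0=1.0)

print(f"{'t (months)':>10} {'exponential':>14} {'Gompertz':>14} {'Gyllenberg-Webb':>16}")
for t in (0.0, 6.0, 12.0, 24.0, 30.0):
    print(
        f"{t:>10.0f} {float(exp_g.volume(t)):>14.4g} "
        f"{float(gom_g.volume(t)):>14.4g} {float(gw_g.volume(t)):>16.4g}"
    )

# the Gompertz curve approaches its carrying capacity
print(f"\nGompertz at t=120 months: {float(gom_g.volume(120.0)):.0f} mm^3 (K=150000)")
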