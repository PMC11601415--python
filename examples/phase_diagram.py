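"""Map the model's phase diagram in the (temperature, inhibition) plane.

Computes the closed-form second-order transition line, the numerically
continued first-order line, and the tricritical point where they meet,
then classifies a few reference points.
"""

import numpy as np

from isingdm import (
    classify_phase,
    first_order_line,
    second_order_eta,
    tricritical_point,
)

T_tri, eta_tri = tricritical_point()
print(f"tricritical point: T = {T_tri:.6f}, eta = {eta_tri:.6f}")
print("  (closed form: T = 1/3, eta = arccosh(2)/3 = 0.438986)")

print("\nsecond-order line eta(T) = T arccosh((1-T)/T):")
for T in (0.1, 0.2, 0.3, 1 / 3, 0.4, 0.5):
    print(f"  T = {T:.3f}  ->  eta_c = {second_order_eta(T):.4f}")

print("\nfirst-order line (exists only below the tricritical temperature):")
fo = first_order_line(np.arange(0.10, 0.33, 0.05))
for T, eta in fo.points:
    print(f"  T = {T:.3f}  ->  eta_fo = {eta:.4f}  "
          f"(band width {eta - second_order_eta(T):.4f})")

print("\nphase classification (stable mean-field velocities):")
for T, eta in [(0.3, 0.05), (0.15, 0.45), (0.29, 0.44), (0.4, 0.6)]:
    print(f"  (T={T}, eta={eta}) -> {classify_phase(T, eta)}")

# The ordered phase supports only a symmetric pair of nonzero decision
# velocities (ballistic decisions); the intermittent band adds a stable
# zero velocity (pauses); the disordered phase has only the zero velocity
# (diffusive decisions). The first-order band is widest at low T and
# pinches off at the tricritical point.
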