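"""Measure p-atic order of single shapes.

Builds a few elementary contours and prints their q_p spectra: a regular
hexagon has perfect hexatic (and triadic-multiple) order, a 2x1 rectangle
has nematic order q_2 = 1/3 with the director along its long axis, and a
circle has no orientational order at all.
"""

import numpy as np

from patic import Contour, ellipse, qp_spectrum, qp_thetap, regular_polygon

shapes = {
    "regular hexagon": regular_polygon(6, circumradius=1.0),
    "2x1 rectangle": Contour([(0, 0), (2, 0), (2, 1), (0, 1)]),
    "equilateral triangle": Contour([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)]),
    "circle (sampled)": ellipse(1.0, 1.0, n=2000),
}

for name, contour in shapes.items():
    spec = qp_spectrum(contour, 6)
    qs = "  ".join(f"q_{p}={q:.4f}" for p, (q, _) in spec.items())
    print(f"{name:22s} {qs}")

q2, theta2 = qp_thetap(shapes["2x1 rectangle"], 2)
print(f"\nrectangle director: q_2 = {q2:.4f}, theta_2 = {theta2:.4f} rad "
      "(0 = long axis along x; q_2 = |b-a|/(a+b) for an a x b rectangle)")
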