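"""From implicit quadric coefficients to clinical parameters.

Takes an ellipsoid with known semi-axes, converts it to the 10 implicit
quadric coefficients and back, and prints the apical curvature radii
(R = a^2/c) and asphericities (Q = (a/c)^2 - 1). A prolate cornea (c > a, b)
has Q < 0; healthy eyes sit near Q = -0.3.
"""

import numpy as np

import corneafit as cf

ellipsoid = cf.CanonicalEllipsoid(semi_axes=(9.32, 9.10, 11.14),
                                  rotation=np.eye(3),
                                  center=np.array([0.0, 0.0, -11.14]))
coeffs = ellipsoid.to_coefficients()
print("implicit coefficients (a11..a00):")
print(np.array2string(coeffs.array, precision=4, suppress_small=True))

back = cf.to_canonical_ellipsoid(coeffs)
m = cf.morpho_parameters(back)
print(f"\nsemi-axes a={back.semi_axes[0]:.3f}  b={back.semi_axes[1]:.3f}  "
      f"c={back.semi_axes[2]:.3f} mm (c along the optical axis)")
print(f"Rx = a^2/c = {m.rx:.3f} mm   Qx = (a/c)^2 - 1 = {m.qx:.4f}")
print(f"Ry = b^2/c = {m.ry:.3f} mm   Qy = (b/c)^2 - 1 = {m.qy:.4f}")
print("\nfq flag for this surface:", cf.check_quadric_order(coeffs),
      "(0 = valid second-order ellipsoidal quadric)")
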