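"""Weighted geometry and scaled distance distribution of a single cell.

Uses the continuum uniform-ball phantom, for which the closed forms are
known: R_g = sqrt(3/5) R and mean scaled distance (3/4) sqrt(5/3) = 0.9682.
"""

import numpy as np

import vesidist as vd

R = 30.0
stack = vd.ball_phantom(radius=R, squash=1.0)
geom = vd.cell_geometry(stack, theta=500.0)
dist = vd.distance_distribution(geom, bins=100, scaled=True)

s = geom.distances / geom.rg
print(f"suprathreshold voxels: {geom.n_pixels}")
print(f"radius of gyration R_g = {geom.rg:.3f}  (R_g/R = {geom.rg / R:.4f}, "
      f"analytic sqrt(3/5) = {np.sqrt(3 / 5):.4f})")
print(f"mean scaled distance <d/R_g> = {np.sum(geom.weights * s):.4f} "
      f"(analytic 0.9682)")
print(f"scaled support ends at s = {s.max():.3f} (analytic sqrt(5/3) = 1.291)")
print()
print("A homogeneous cell yields a unimodal density rising like 3 s^2 up to")
print("s_max = sqrt(5/3); deviations from this shape signal non-uniform")
print("vesicle placement.")
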