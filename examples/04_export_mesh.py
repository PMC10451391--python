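"""Fit a surface and export the reconstructed cap as a binary STL mesh.

The mesh samples the fitted quadric over a 4 mm polar footprint, triangulates
it by Delaunay in the corneal plane, and writes millimetre-unit binary STL
suitable for CAD inspection.
"""

from pathlib import Path

import corneafit as cf

grid, _ = cf.make_ellipsoid_grid(cf.SyntheticSpec(noise_sigma=0.003, seed=3))
result = cf.fit_lsq_trra(cf.polar_to_cartesian(grid))
print(f"fit: MSE {result.mse:.3e} mm^2, fq={result.fq}")

out = Path("reconstructed_cap.stl")
cf.export_stl(result.coefficients, footprint_radius=4.0, resolution=32,
              path=out)
verts, faces = cf.sample_cap(result.coefficients, 4.0, 32)
print(f"wrote {out} ({len(verts)} vertices, {len(faces)} triangles, units mm)")
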