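# corneafit

Modal reconstruction of corneal surfaces from sparse, incomplete elevation
point clouds, for researchers working with Scheimpflug tomography data.

Corneal tomographers of the Sirius family export one surface (anterior or
posterior) as a polar elevation grid: 24 rings spaced 0.2 mm by 256
semi-meridians, 6144 nodes per surface, with the sentinel value −1000 marking
samples lost to tear-film instability or acquisition noise. Clinically useful
morpho-geometric parameters — apical curvature radii and asphericity — require
a smooth global model of that cap, and the standard approach fits the ten
coefficients a\_ij of a general implicit quadric

    Q(x, y, z) = a11 x² + a12 xy + a13 xz + a10 x
               + a22 y² + a23 yz + a20 y
               + a33 z² + a30 z + a00 = 0

to the Cartesian point cloud by minimising the mean squared algebraic
residual (1/N) Σ Q(P_s)², subject to a unit-norm constraint on the
coefficient vector (the zero vector is otherwise a trivial minimiser).
Iterative local fitters are sensitive to gaps and local deformations
(keratoconus cones), so the central fitter here is an **elitist real-coded
genetic algorithm** over the ten coefficients — population 1000 (100 per
variable), crossover rate 0.8, elite/cloning rate 0.2, zero mutation,
tournament selection and rotation-invariant blend crossover — together with
classical baselines (closed-form SVD fit, trust-region reflective least
squares, SQP). A fitted quadric is reduced to canonical ellipsoid form
x′²/a² + y′²/b² + z′²/c² = 1, from which

    Rx = a²/c,  Ry = b²/c,  Qx = (a/c)² − 1,  Qy = (b/c)² − 1.

Goodness of fit is the elevation mean squared error (mm²) between the
measured elevations and the quadric re-evaluated at the same nodes; a fit
whose quadric is not a real second-order ellipsoid is a quadric-order failure
(fq = 1), and the failure count over a batch is the FQN.

Real patient exports are not redistributable, so the package includes a
synthetic generator producing tomographer-style grids from ellipsoids with
prescribed (Rx, Ry, Qx, Qy), Gaussian elevation noise, sentinel dropout
(random / wedge / peripheral-ring) and Gaussian cone deformations emulating
keratoconus, with exact ground truth for validation.

## Worked example

```python
import corneafit as cf

spec = cf.SyntheticSpec(rx=7.8, ry=7.8, qx=-0.3, qy=-0.3,
                        noise_sigma=0.005, seed=42)
grid, truth = cf.make_ellipsoid_grid(spec)
cloud = cf.polar_to_cartesian(grid)

ga = cf.fit_ga(cloud, seed=1)
m = cf.morpho_parameters(cf.to_canonical_ellipsoid(ga.coefficients))
print(ga.mse, m.rx, m.qx)
```

Running `python examples/01_simulate_and_fit.py` (this exact scenario)
prints:

```
cloud: 6144 points from 6144 grid nodes
GA     : MSE 2.518e-05 mm^2, fq=0, 739 generations, converged=True
DIRECT : MSE 2.518e-05 mm^2  (noise floor sigma^2 = 2.5e-05)
recovered Rx 7.8078 mm (truth 7.8000), Qx -0.2924 (truth -0.3000)
recovered Ry 7.8052 mm (truth 7.8000), Qy -0.2927 (truth -0.3000)
```

The elevation MSE of both fitters sits at the injected noise floor
σ² = 2.5×10⁻⁵ mm² — with 5 µm noise no fit can do better — and the recovered
radii agree with truth to ~0.1%, the asphericities to <0.01. The other
scripts in `examples/` cover batch method comparison across graded cohorts,
the quadric→ellipsoid→(R, Q) reduction, and STL mesh export.

A thin CLI wraps the same library calls:

```bash
corneafit simulate --preset ak2 -n 5 --seed 1 --out-dir sims
corneafit fit sims/ak2_000.csv --method ga --seed 1 --out fit.json
corneafit compare --in-dir sims --methods ga,lsq --seed 1 --out table.csv
corneafit export fit.json --radius 4 --out cap.stl
```

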