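"""Batch comparison of fitting methods over graded synthetic cohorts.

Generates small control and keratoconus-like cohorts (Gaussian cone
deformations of growing amplitude, asphericity drawn toward -1), fits each
surface with the least-squares and direct baselines, and prints the per
method x group table of elevation MSE, failure count (FQN) and mean
morphometric parameters -- the structure used to compare reconstruction
methods across disease grades.
"""

import corneafit as cf

grids, groups = [], []
for preset in ("control", "ak2"):
    for grid, _ in cf.make_cohort(3, preset, seed=11):
        grids.append(grid)
        groups.append(preset)

table = cf.compare_methods(grids, methods=("LSQ", "DIRECT"), groups=groups,
                           seed=1)
print(table.to_string(index=False))
print("\nmse_mean ~ noise floor (9e-6 control, 2.5e-5 ak2); the ak2 rows sit"
      "\nabove it because the cone is outside the quadric model family."
      "\nfqn = 0 means every fit produced a valid ellipsoidal quadric.")
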