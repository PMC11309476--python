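"""Derive growth-rate and cell-volume traits from raw measurements.

Simulates triplicate fluorescence growth curves for one strain, extracts
the maximum specific growth rate by the linear (sliding-window log-linear)
method, converts it to a doubling time, and computes geometric biovolumes
for a few cell shapes, including the height-from-diameter fallback rules.
"""

from nucleotype.simulate import sim_growth_curve
from nucleotype.traits import (
    CellShapeSpec,
    cell_volume,
    doubling_time,
    max_growth_rate,
    strain_doubling_time,
)

print("growth curves (true mu = 0.30 / h):")
mus = []
for rep in range(3):
    curve = sim_growth_curve(mu=0.30, lag_h=12, carrying_capacity=400,
                             noise_cv=0.02, dt_h=6, n_points=16, seed=rep)
    mu = max_growth_rate(curve, window=4, r2_min=0.95)
    mus.append(mu)
    print(f"  replicate {rep + 1}: mu = {mu:.3f} /h, "
          f"T_d = {doubling_time(mu):.2f} h")

print(f"strain mean doubling time: {strain_doubling_time(mus):.2f} h "
      f"(truth ln2/0.3 = {0.693 / 0.3:.2f} h)")

print("\ncell volumes:")
shapes = [
    ("small centric, height unknown",
     CellShapeSpec("cylinder", diameter_um=10, height_rule="half_diameter")),
    ("chain-former (height = diameter)",
     CellShapeSpec("cylinder", diameter_um=8, height_rule="equal_diameter")),
    ("spherical cell", CellShapeSpec("sphere", diameter_um=10)),
    ("elongate pennate",
     CellShapeSpec("prolate_spheroid", diameter_um=6, height_um=18)),
]
for label, spec in shapes:
    print(f"  {label}: {cell_volume(spec):8.1f} um^3")
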