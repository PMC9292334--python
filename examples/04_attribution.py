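"""Variance attribution with LMG shares on a panel with known truth.

Generates a region-structured synthetic panel from the four-driver linear
model, fits it, decomposes the explained variance per driver, and compares
against the exact population shares implied by the generating covariance.
"""

import numpy as np

from zoometals import (
    PanelSpec,
    RegionSpec,
    attribute_by_group,
    generate_driver_panel,
    lmg_shares,
    population_shares,
)

rng = np.random.default_rng(0)
a = rng.standard_normal((4, 4))
spec = PanelSpec(
    n_per_region=5000,
    regions=[RegionSpec("GYRE", np.zeros(4), a @ a.T + np.eye(4))],
    coefficients=(0.5, 1.5, 0.2, 2.0),  # zoo biomass engineered dominant
    target_r2=0.7,
    seed=42,
)
panel, truth = generate_driver_panel(spec)

emp = lmg_shares(panel)
pop = population_shares(spec).population_shares
print("driver variance shares (fraction of response variance):")
for p in ("fq", "prey_q", "sst", "zoo_b"):
    print(f"  {p:7s} empirical {emp.shares[p]:.3f} | analytic {pop[p]:.3f}")
print(f"model R^2: {emp.r_squared:.3f} (shares sum to it exactly)")

res = attribute_by_group(panel, by=["region"])
row = res.table.iloc[0]
print(f"dominant biotic driver: {row['dominant']} "
      f"(ternary coords qual={row['qual']:.2f}, quant={row['quant']:.2f}, "
      f"zoo={row['zoo']:.2f}; temperature share {row['temperature_share']:.3f})")
print(
    "interpretation: LMG averages each driver's sequential R^2 gain over "
    "all orderings, so correlated drivers split their shared variance "
    "instead of one absorbing it."
)
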