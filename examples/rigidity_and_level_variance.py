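"""Spectral rigidity and level number variance of reference ensembles.

Compares the two RMT observables on a GOE spectrum (rigid, correlated
levels) and a Poisson spectrum (uncorrelated levels) against their
closed-form limits: Poisson has Delta3(L) = L/15 and Sigma2(L) = L, while
GOE grows only logarithmically.
"""

import numpy as np

from rmtfc import (
    level_variance,
    simulate_goe,
    simulate_poisson_levels,
    spectral_rigidity,
    unfold,
)

L = np.arange(1, 21, dtype=float)

goe = unfold(simulate_goe(2000, seed=1), degree=9)
pois = simulate_poisson_levels(2000, seed=1)  # unfolded by construction

goe_rig = spectral_rigidity(goe, L, seed=1)
poi_rig = spectral_rigidity(pois, L, seed=1)
goe_lv = level_variance(goe, L, seed=1)
poi_lv = level_variance(pois, L, seed=1)

print(f"{'L':>3} {'GOE D3':>8} {'Poisson D3':>11} {'L/15':>6} "
      f"{'GOE S2':>8} {'Poisson S2':>11}")
for i, ell in enumerate(L[::5]):
    j = int(ell) - 1
    print(f"{ell:3.0f} {goe_rig.values[j]:8.3f} {poi_rig.values[j]:11.3f} "
          f"{ell / 15:6.3f} {goe_lv.values[j]:8.3f} {poi_lv.values[j]:11.3f}")

print(
    "\nPoisson tracks its closed forms (D3 ~ L/15, S2 ~ L); GOE sits far "
    "below both: level repulsion makes the spectrum rigid. Each value is a "
    "Monte-Carlo average over window starts, sampled until its standard "
    "error is below 1% (n_centers per L: "
    f"{goe_rig.n_centers.min()}..{goe_rig.n_centers.max()})."
)
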