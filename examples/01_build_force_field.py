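"""Build the grid force field for a toy barrel and inspect it.

Constructs the charged beta-barrel-like stationary body, collapses its
LJ parameters into the three element categories, builds the
electrostatic and LJ potential maps on a 1 A grid, and deposits the
mobile probe's density grids.
"""

import numpy as np

from rigidbd import (
    ToyBodySpec,
    build_density_set,
    build_map_set,
    collapse_lj_categories,
    make_anchor_probe,
    make_toy_barrel,
)
from rigidbd.gridmaps import frame_around, interpolate

barrel = make_toy_barrel(ToyBodySpec(patch_charge=10.0))
probe, anchors = make_anchor_probe(ToyBodySpec(kind="anchor-probe",
                                               probe_charge=-8.0))

print(f"barrel: {len(barrel)} atoms, total charge {barrel.total_charge:+.1f} e")
print(f"probe:  {len(probe)} atoms, total charge {probe.total_charge:+.1f} e")

for cat in collapse_lj_categories(barrel):
    print(f"LJ category {cat.label:>4}: {cat.n_members:3d} atoms, "
          f"Rmin {cat.rmin_mean:.2f} A, eps(scaled) {cat.eps_scaled:.4f} kcal/mol")

frame = frame_around(barrel, spacing=1.0, margin=20.0)
maps = build_map_set(barrel, frame, solvent_dielectric=78.0, cutoff=34.0)
density = build_density_set(probe, spacing=1.0)

# the electrostatic potential just outside the charged patch (at x = +17 A,
# rim height) is positive; the opposite rim side is neutral
v_patch = interpolate(maps.elec_potential, (17.0, 0.0, 17.5))
v_far = interpolate(maps.elec_potential, (-17.0, 0.0, 17.5))
print(f"potential at patch {v_patch:+.3f}, opposite side {v_far:+.3f} kcal/(mol e)")
print(f"charge-density cells: {len(density.charge_cells[1])}, "
      f"total {density.charge_density.values.sum():+.3f} e (conserved)")
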