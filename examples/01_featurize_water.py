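"""Build a water monomer and print its atomic-local-frame features.

Each atom owns a right-handed frame built from two bonded reference atoms;
the resulting 3N-6 features (bond, bond, angle for a triatomic) are invariant
to rotating or translating the molecule, which is what makes them usable as
machine-learning inputs.
"""

import numpy as np

from crystalgp.alf import compute_alf, featurize
from crystalgp.fixtures import _random_rotation, toy_monomer

water = toy_monomer()
print("atoms:", water.elements)

for center in range(3):
    alf = compute_alf(water, center)
    feats = featurize(water, center, alf)
    print(f"atom {center} ({water.elements[center]}): "
          f"A_x={alf.x_axis_atom} A_xy={alf.plane_atom} features={np.round(feats, 4)}")

# rotate + translate: the features do not move
rng = np.random.default_rng(0)
moved = water.copy()
moved.positions = water.positions @ _random_rotation(rng).T + [5.0, -2.0, 1.0]
alf = compute_alf(water, 0)
drift = np.abs(featurize(moved, 0, alf) - featurize(water, 0, alf)).max()
print(f"feature drift under a rigid motion: {drift:.2e}  (rotation/translation invariant)")
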