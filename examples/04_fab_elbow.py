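"""Fab elbow plasticity: the residual rotation of the constant module.

Crystallographically independent copies of one Fab differ mainly by a hinge
rotation at the elbow between the variable (V) and constant (C) modules. The
measurement: align two copies on their V-module C-alphas, then fit the
C modules — the rotation still separating them is the elbow swing.
"""

import numpy as np

from interfab import elbow_swing
from interfab.fixtures import _rotation_about_axis, make_hinged_fab

v_region = {"F": (1, 30)}    # variable module: residues 1-30
c_region = {"F": (31, 60)}   # constant module: residues 31-60

for angle in (0.0, 12.5, 30.0):
    base, swung = make_hinged_fab(angle, seed=11)
    result = elbow_swing([base, swung], v_region, c_region)
    print(f"planted hinge {angle:5.1f} deg -> measured {result['max_deg']:7.3f} deg")

# the measurement is invariant to any global rigid motion of either copy
base, swung = make_hinged_fab(30.0, seed=11)
moved = swung.transformed(_rotation_about_axis(np.array([1.0, 2.0, 0.5]), 77.0),
                          np.array([10.0, -5.0, 3.0]))
result = elbow_swing([base, moved], v_region, c_region)
print(f"after a global 77 deg rotation of copy 2: still {result['max_deg']:.3f} deg")
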