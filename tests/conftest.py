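import numpy as np
import pytest

from interfab.contacts import InterfaceCriteria
from interfab.fixtures import PlantedContact, make_toy_complex
from interfab.model import ROLE_ANTIGEN, ROLE_HEAVY, ROLE_LIGHT, Selection
from interfab.structure_io import assign_radii


@pytest.fixture
def antigen_sel():
    return Selection.by_role(ROLE_ANTIGEN)


@pytest.fixture
def binder_sel():
    return Selection.by_role(ROLE_HEAVY, ROLE_LIGHT)


@pytest.fixture
def full_toy():
    """One planted contact of every category, radii assigned."""
    model, inventory = make_toy_complex(
        [
            PlantedContact("hydrogen_bond", 2.9),
            PlantedContact("salt_bridge", 3.5),
            PlantedContact("salt_bridge_bidentate", 3.5),
            PlantedContact("vdw", 3.8),
            PlantedContact("water_bridge", water_gaps=(2.8, 2.9)),
        ]
    )
    assign_radii(model)
    return model, inventory


@pytest.fixture
def criteria():
    return InterfaceCriteria()


def random_planted_spec(rng: np.random.Generator) -> list[PlantedContact]:
    """A random planted-contact spec staying clear of the cutoff boundaries."""
    windows = {
        "hydrogen_bond": (2.6, 3.4),
        "salt_bridge": (3.1, 3.9),
        "salt_bridge_bidentate": (3.1, 3.9),
        "vdw": (3.55, 3.95),
    }
    categories = list(windows) + ["water_bridge", "hbond_as_vdw"]
    planted = []
    for _ in range(rng.integers(1, 6)):
        cat = categories[rng.integers(0, len(categories))]
        if cat == "water_bridge":
            planted.append(
                PlantedContact(
                    "water_bridge",
                    water_gaps=(rng.uniform(2.6, 3.3), rng.uniform(2.6, 3.3)),
                )
            )
        elif cat == "hbond_as_vdw":
            # donor/acceptor geometry just beyond the H-bond cutoff
            planted.append(PlantedContact("hydrogen_bond", rng.uniform(3.55, 3.95)))
        else:
            lo, hi = windows[cat]
            planted.append(PlantedContact(cat, round(float(rng.uniform(lo, hi)), 3)))
    return planted
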