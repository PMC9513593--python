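"""Shared fixtures: tiny desk-scale geometries and phantoms that keep
simulation and reconstruction tests fast."""

import pytest

from lutac.geometry import (SinogramSpec, build_lor_table, build_scanner,
                            desk_variant)
from lutac.grid import Grid
from lutac.phantom import BodySpec, Organ, build_phantom
from lutac.projector import chord_lengths, place_endpoints


@pytest.fixture(scope="session")
def tiny_geometry():
    """40 crystals/ring, 3 rings/unit: policy math is exact, sinograms
    are small."""
    return desk_variant(build_scanner("uexplorer"), crystals_per_ring=40,
                        rings_per_unit=3)


@pytest.fixture(scope="session")
def tiny_grid():
    return Grid(shape=(20, 20, 40), voxel_size=8.0)


@pytest.fixture(scope="session")
def tiny_body():
    """A small torso: water body, one lung, a liver blob, hot bladder."""
    organs = (
        Organ("body", "cylinder", (0, 0, 0), (60, 50, 140), "soft_tissue"),
        Organ("lung", "ellipsoid", (-25, 0, 60), (22, 28, 50), "lung"),
        Organ("liver", "ellipsoid", (22, 5, -20), (28, 28, 40), "liver"),
        Organ("bladder", "sphere", (0, 0, -100), (24,), "water",
              activity_override=10.0),
    )
    return BodySpec(organs=organs, total_activity_mbq=5.0,
                    grid_shape=(20, 20, 40), voxel_size=8.0)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_body):
    return build_phantom(tiny_body)


def make_table(geometry, grid, tof=False, angle_mash=1, max_angle=None,
               axial_mash=3):
    spec = SinogramSpec.for_geometry(geometry, tof=tof, angle_mash=angle_mash,
                                     axial_mash=axial_mash,
                                     max_acceptance_angle=max_angle)
    tab = place_endpoints(build_lor_table(geometry, spec))
    return tab.restrict(chord_lengths(tab.front_a, tab.front_b, grid) > 0)


@pytest.fixture(scope="session")
def tiny_table(tiny_geometry, tiny_grid):
    return make_table(tiny_geometry, tiny_grid)


@pytest.fixture(scope="session")
def tiny_tof_table(tiny_geometry, tiny_grid):
    return make_table(tiny_geometry, tiny_grid, tof=True)


@pytest.fixture(scope="session")
def small_geometry():
    """Denser small variant for recovery-type tests (finer axial and
    radial sampling than the tiny fixture)."""
    return desk_variant(build_scanner("uexplorer"), crystals_per_ring=60,
                        rings_per_unit=9)


@pytest.fixture(scope="session")
def small_tof_table(small_geometry, tiny_grid):
    return make_table(small_geometry, tiny_grid, tof=True, axial_mash=1)
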