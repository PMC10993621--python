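import numpy as np
import pytest

from microdyn import SimulationConfig, render_cell
from microdyn.morphology import partition_cell


@pytest.fixture
def star_config():
    """A single four-ray cell with straight processes: exact geometry known."""
    return SimulationConfig(
        field_size_px=(256, 256),
        pixel_size_um=0.5,
        n_cells=1,
        soma_radius_um=5.0,
        n_branches_per_cell=4,
        branch_length_um=30.0,
        branch_tortuosity=0.0,
        min_soma_separation_um=10.0,
        seed=0,
    )


@pytest.fixture
def star_mask(star_config):
    """Binary mask of the star cell centered in a 128 um field."""
    return render_cell((64.0, 64.0), star_config).astype(bool)


@pytest.fixture
def star_cell(star_mask, star_config):
    return partition_cell(star_mask, star_config.pixel_size_um,
                          soma_seed_um=(64.0, 64.0))


def draw_disk_mask(shape, center_rc, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 < radius_px**2
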