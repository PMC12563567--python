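import numpy as np
import pytest

from vespos.ioutil import CellROI
from vespos.synthio import PunctaSpec, SceneSpec, generate_scene


def make_disk_roi(cell_radius=100, nucleus_radius=20, cell_id=1, pad=4):
    """Disk cell with a concentric disk nucleus, on a tight frame."""
    n = 2 * (cell_radius + pad)
    rr, cc = np.ogrid[0:n, 0:n]
    d2 = (rr - n / 2) ** 2 + (cc - n / 2) ** 2
    cell = d2 <= cell_radius ** 2
    nuc = d2 <= nucleus_radius ** 2
    return CellROI(cell_id=cell_id, cell_mask=cell, nucleus_mask=nuc,
                   clone=True)


@pytest.fixture(scope="session")
def disk_roi():
    return make_disk_roi()


@pytest.fixture(scope="session")
def perinuclear_scene():
    """Default mosaic scene, every cell clone-positive, perinuclear puncta."""
    spec = SceneSpec(seed=42, clone_fraction=1.0)
    return generate_scene(spec, [PunctaSpec(mode="perinuclear", n_spots=50)])


@pytest.fixture(scope="session")
def uniform_scene():
    spec = SceneSpec(seed=7, clone_fraction=1.0)
    return generate_scene(spec, [PunctaSpec(mode="uniform", n_spots=80)])
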