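import numpy as np
import pytest

from specklemain import imaging, scenes, speckle
from specklemain.optics import paper_unit_cell
from specklemain.roughsurf import generate_height_map


@pytest.fixture(scope="session")
def hmm_stack():
    return speckle.illumination_stack()


@pytest.fixture(scope="session")
def unit_cell():
    return paper_unit_cell()


@pytest.fixture(scope="session")
def transfer_488(hmm_stack, unit_cell):
    """Radial stack transfer at 488 nm, shared across tests (expensive)."""
    return speckle.StackTransfer(hmm_stack, 488.0, cell=unit_cell)


@pytest.fixture(scope="session")
def rough_128():
    return generate_height_map(128, 5.0, 1.1, 35.0, seed=7)


@pytest.fixture(scope="session")
def small_speckle_stack(hmm_stack, transfer_488, rough_128):
    """A small but complete simulated acquisition: 2 beads at 120 nm,
    16 camera pixels at 40 nm (binning 8 from a 5 nm fine grid), 40 frames.

    Session-scoped because several metric/reconstruction tests reuse it.
    """
    scene = scenes.two_bead_scene(120.0, dx_f=5.0, n=128)
    pats = [
        speckle.speckle_pattern(
            speckle.incident_field(488.0, 0.2, 64, seed=300 + m),
            hmm_stack,
            rough_128,
            transfer=transfer_488,
        )
        for m in range(40)
    ]
    psf_sim = imaging.widefield_psf(1.5, 520.0, 5.0)
    stack = imaging.acquire_stack(
        scene, pats, psf_sim, binning=8, photons_scale=5000.0,
        background=5.0, read_sd=2.0, seed=11,
    )
    return scene, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
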