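import numpy as np
import pytest

from spedose.beams import BeamSpec
from spedose.materials import get_material
from spedose.phantoms import make_slab_phantom
from spedose.transport import TransportConfig, run_transport
from spedose.unfold import Spectrum


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def small_water_grid():
    """4 cm water cube, 1 mm depth resolution — shared across transport tests."""
    return make_slab_phantom("water", (4.0, 3.0, 3.0), (0.1, 0.15, 0.15))


@pytest.fixture(scope="session")
def proton_dose_30mev(small_water_grid):
    """One 30 MeV parallel-beam batch on the shared water grid (warm kernel)."""
    beam = BeamSpec(particle="proton", spectrum=Spectrum.monoenergetic(30.0),
                    parallel=True, field_halfwidth=1.0)
    cfg = TransportConfig(n_histories=3000, base_seed=42)
    dose, stats = run_transport(small_water_grid, beam, cfg, seed=42,
                                return_stats=True)
    return dose, stats, beam, cfg
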