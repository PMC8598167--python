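import numpy as np
import pytest

from chromofold.fiber_model import build_initial_fiber
from chromofold.presets import desk_force_field
from chromofold.synthetic_data import (
    SyntheticFiberSpec,
    generate_nucleosome_track,
)


@pytest.fixture(scope="session")
def desk_ff():
    return desk_force_field()


@pytest.fixture(scope="session")
def small_fiber(desk_ff):
    """A 4-nucleosome fiber with mixed acetylation and LH occupancy."""
    spec = SyntheticFiberSpec(
        n_nucleosomes=4, repeat_jitter_sd=0.0, acetylation_density=0.5,
        lh_density=0.5, seed=1,
    )
    return build_initial_fiber(generate_nucleosome_track(spec), desk_ff)


def make_fiber(n=4, acet=0.0, lh=0.0, seed=1, ff=None, jitter=0.0):
    spec = SyntheticFiberSpec(
        n_nucleosomes=n, repeat_jitter_sd=jitter, acetylation_density=acet,
        lh_density=lh, seed=seed,
    )
    return build_initial_fiber(
        generate_nucleosome_track(spec), ff or desk_force_field()
    )


@pytest.fixture(scope="session")
def plain_fiber():
    """A 4-nucleosome fiber with no acetylation and no LH."""
    return make_fiber()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
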