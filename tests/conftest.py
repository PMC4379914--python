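import numpy as np
import pytest

import locustphase as lp


@pytest.fixture(scope="session")
def geom() -> lp.ArenaGeometry:
    return lp.GEOMETRY_PRESETS["open-area"]


@pytest.fixture(scope="session")
def zones(geom):
    return lp.build_zones(geom)


@pytest.fixture(scope="session")
def model() -> lp.LogisticModel:
    return lp.published_model()


def uniform_trajectory(rng, geom, n=100, dt=0.2, animal_id="", arm_label=""):
    """A valid trajectory with iid-uniform in-arena positions.

    Harsher than a continuous walk for zone bookkeeping (it crosses zone
    boundaries constantly) and almost surely avoids exact boundaries.
    """
    positions = np.column_stack(
        [
            rng.uniform(0.0, geom.open_length_x, n),
            rng.uniform(0.0, geom.width_y, n),
        ]
    )
    times = np.arange(n) * dt
    return lp.Trajectory(times, positions, animal_id=animal_id, arm_label=arm_label)


@pytest.fixture
def make_uniform_trajectory(geom):
    def factory(seed, n=100, dt=0.2):
        return uniform_trajectory(np.random.default_rng(seed), geom, n=n, dt=dt)

    return factory
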