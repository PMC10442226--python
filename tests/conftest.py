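import numpy as np
import pytest

from tagan.io import make_fixtures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bundle():
    """Deterministic fixture bundle shared across the suite."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def tiny_training_set():
    """50 simulated confocal/STED pairs with localization targets."""
    from tagan import simulate as sim
    from tagan.annotate import cubic_root_localization_map

    rng = np.random.default_rng(7)
    items = []
    for i in range(50):
        dm = sim.random_datamap(rng, (i % 6) + 1)
        conf = sim.render_image(dm, sim.CONFOCAL, rng).pixels.astype(float)
        sted = sim.render_image(dm, sim.STED, rng).pixels.astype(float)
        loc = cubic_root_localization_map(dm.centers, dm.shape)
        items.append(
            {
                "lr": conf / max(conf.max(), 1.0),
                "hr": sted / max(sted.max(), 1.0),
                "annotation": loc / loc.max(),
            }
        )
    return items
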