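import pytest

import agrifoodsim as afs


@pytest.fixture(scope="session")
def world():
    return afs.build_world(seed=1)


@pytest.fixture(scope="session")
def calib(world):
    return afs.calibrate(world)


@pytest.fixture(scope="session")
def bundles(world, calib):
    """The three default scenario runs on the seed-1 world."""
    return afs.run_all(world, calib)


@pytest.fixture(scope="session")
def fixtures():
    return afs.load_paper_fixtures()
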