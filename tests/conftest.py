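import pytest

from netpharm.sdtnbi import FingerprintMatrix, KnownDTISet, build_sdt_network
from netpharm.synthetic import SimConfig, simulate
from netpharm.workflow import run_pipeline


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The standard synthetic study bundle (default config, seed 1)."""
    root = tmp_path_factory.mktemp("bundle")
    return simulate(SimConfig(seed=1), root)


@pytest.fixture(scope="session")
def default_pipeline(default_bundle, tmp_path_factory):
    """Full analysis chain run once on the standard bundle."""
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(default_bundle.root, out)


@pytest.fixture
def tiny_network():
    """3 drugs, 2 targets, 3 bits with hand-countable degrees.

    d1: t1, b1, b2   d2: t1, t2, b2   d3: b3 (NCE)
    """
    dtis = KnownDTISet({("d1", "t1"), ("d2", "t1"), ("d2", "t2")})
    fps = FingerprintMatrix(
        ["d1", "d2", "d3"],
        ["b1", "b2", "b3"],
        [[1, 1, 0], [0, 1, 0], [0, 0, 1]],
    )
    return build_sdt_network(dtis, fps)
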