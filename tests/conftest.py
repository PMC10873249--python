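import pytest

from mutorder import absorption_statistics, make_scenario, propagate_exact
from mutorder.bistable import AutoregCubic


@pytest.fixture(scope="session")
def cubic():
    return AutoregCubic.default()


@pytest.fixture(scope="session")
def exact_n100():
    """Exact absorption distributions and statistics at n=100, per scenario."""
    out = {}
    for name in "ABC":
        dist = propagate_exact(make_scenario(name, n=100))
        out[name] = (dist, absorption_statistics(dist))
    return out
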