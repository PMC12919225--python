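import numpy as np
import pytest

from caliberflow.network import RateNetwork, build_frame


@pytest.fixture
def net2s():
    """Symmetric unit-rate 2-state network (the reference process itself)."""
    return RateNetwork(("1", "2"), {("1", "2"): 1.0, ("2", "1"): 1.0})


@pytest.fixture
def net2a():
    """Asymmetric 2-state network: k12=2, k21=1 (telegraph process)."""
    return RateNetwork(("1", "2"), {("1", "2"): 2.0, ("2", "1"): 1.0})


@pytest.fixture
def net3c():
    """3-state ring, forward rates 2, backward rates 1 (driven cycle)."""
    return RateNetwork(
        ("1", "2", "3"),
        {("1", "2"): 2.0, ("2", "3"): 2.0, ("3", "1"): 2.0,
         ("2", "1"): 1.0, ("3", "2"): 1.0, ("1", "3"): 1.0},
    )


@pytest.fixture
def framed(request):
    """Helper: (net, frame) for the fixture named in request.param."""
    net = request.getfixturevalue(request.param)
    return net, build_frame(net)


def rel_err(a, b, floor=1.0):
    """Error of a vs b relative to the larger scale present."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    scale = max(np.abs(a).max(initial=0.0), np.abs(b).max(initial=0.0), floor)
    return float(np.abs(a - b).max() / scale)
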