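import numpy as np
import pytest

from ugfc.enhancement import default_rule_base


@pytest.fixture(scope="session")
def rules():
    return default_rule_base()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_sdf(n: int, cx: float, cy: float, r: float) -> np.ndarray:
    """Analytic signed distance function of a disk (negative inside)."""
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(xx - cx, yy - cy) - r
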