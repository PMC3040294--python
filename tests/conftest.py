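import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mapfdr

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    return mapfdr.AreaTable(["A01", "A02", "A03"], [10, 0, 5], [8.2, 1.0, 5.0])


@pytest.fixture
def lattice3():
    """3x3 rook lattice with a matching area table (y drawn at the null)."""
    ids, adj = mapfdr.lattice_adjacency(3, 3)
    rng = np.random.default_rng(7)
    e = np.full(9, 10.0)
    return mapfdr.AreaTable(ids, rng.poisson(e), e), adj


@pytest.fixture
def null_map():
    """287-area synthetic map with every area truly at the null."""
    return mapfdr.generate_map(pi0_true=1.0, seed=11)


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text)
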