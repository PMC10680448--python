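import numpy as np
import pytest

from reefguest.io_tables import IncidenceMatrix, InteractionRecord


@pytest.fixture
def staircase():
    """Perfectly nested 4x4 matrix with all-distinct marginals."""
    cells = np.array(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], dtype=np.int8
    )
    return IncidenceMatrix(hosts=list("abcd"), guests=list("wxyz"), cells=cells)


@pytest.fixture
def all_ones():
    return IncidenceMatrix(
        hosts=["h1", "h2"], guests=["g1", "g2"], cells=np.ones((2, 2), dtype=np.int8)
    )


@pytest.fixture
def two_block():
    """Two complete 2x2 blocks; optimal Barber partition has Q = 0.5."""
    cells = np.array(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=np.int8
    )
    return IncidenceMatrix(hosts=list("abcd"), guests=list("wxyz"), cells=cells)


@pytest.fixture
def random_matrix():
    """Factory for seeded random incidence matrices with no empty margins."""

    def make(r=6, c=8, p=0.4, seed=0):
        rng = np.random.default_rng(seed)
        while True:
            cells = (rng.random((r, c)) < p).astype(np.int8)
            if cells.sum(axis=1).min() > 0 and cells.sum(axis=0).min() > 0:
                return IncidenceMatrix(
                    hosts=[f"h{i}" for i in range(r)],
                    guests=[f"g{j}" for j in range(c)],
                    cells=cells,
                )

    return make


def make_record(host, guest, eco="Floridian", lat=20.0, lon=-80.0, ref="ref_a"):
    return InteractionRecord(
        host_species=host,
        guest_species=guest,
        ecoregion=eco,
        latitude=lat,
        longitude=lon,
        reference=ref,
    )


@pytest.fixture
def record_factory():
    return make_record
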