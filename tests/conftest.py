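import numpy as np
import pytest

from c3net import ConnectivityMatrix, MIMatrix

# 4-gene worked example: MI values and their significance mask
WORKED_I = np.array(
    [
        [0.0, 0.7, 0.9, 0.8],
        [0.7, 0.0, 0.6, 0.5],
        [0.9, 0.6, 0.0, 0.1],
        [0.8, 0.5, 0.1, 0.0],
    ]
)
WORKED_C = np.array(
    [
        [0, 1, 1, 1],
        [1, 0, 1, 0],
        [1, 1, 0, 0],
        [1, 0, 0, 0],
    ]
)
WORKED_IDS = ["g1", "g2", "g3", "g4"]


@pytest.fixture
def worked_mi() -> MIMatrix:
    return MIMatrix(list(WORKED_IDS), WORKED_I.copy())


@pytest.fixture
def worked_conn() -> ConnectivityMatrix:
    return ConnectivityMatrix(list(WORKED_IDS), WORKED_C.copy())


def random_mi_conn(rng: np.random.Generator, n: int) -> tuple[MIMatrix, ConnectivityMatrix]:
    """A random symmetric MI matrix and a random significance mask."""
    vals = rng.uniform(0.0, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    conn = (rng.random((n, n)) < 0.5).astype(int)
    conn = np.minimum(conn, conn.T)
    np.fill_diagonal(conn, 0)
    ids = [f"g{i}" for i in range(n)]
    return MIMatrix(ids, vals), ConnectivityMatrix(ids, conn)
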