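import datetime as dt

import numpy as np
import pytest

from roostnet import AntennaRegistry, AssociationMatrix, DetectionEvent, StudyWindow


@pytest.fixture
def registry() -> AntennaRegistry:
    """Two roosts, one entry and two ceiling antennas each."""
    return AntennaRegistry(
        roost_of={
            "R0_E0": "R0", "R0_C0": "R0", "R0_C1": "R0",
            "R1_E0": "R1", "R1_C0": "R1", "R1_C1": "R1",
        },
        role_of={
            "R0_E0": "entry", "R0_C0": "ceiling", "R0_C1": "ceiling",
            "R1_E0": "entry", "R1_C0": "ceiling", "R1_C1": "ceiling",
        },
    )


@pytest.fixture
def season() -> StudyWindow:
    return StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 8, 15))


def ev(ts: str, tag: str, ant: str) -> DetectionEvent:
    return DetectionEvent(dt.datetime.fromisoformat(ts), tag, ant)


def binary_matrix(adj: np.ndarray, kind: str = "cohabitation") -> AssociationMatrix:
    """AssociationMatrix over nodes n0, n1, ... from a 0/1 adjacency array."""
    adj = np.asarray(adj, dtype=int)
    nodes = tuple(f"n{i}" for i in range(adj.shape[0]))
    return AssociationMatrix(nodes, adj, kind)


def random_binary_matrix(n: int, p: float, rng: np.random.Generator,
                         kind: str = "cohabitation") -> AssociationMatrix:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return binary_matrix((adj | adj.T).astype(int), kind)
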