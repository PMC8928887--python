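import numpy as np
import pytest
from hypothesis import settings

from adbm import Community, PredationMatrix

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_community(masses, labels=None):
    masses = list(masses)
    if labels is None:
        labels = [chr(ord("A") + k) for k in range(len(masses))]
    return Community.from_data(labels, masses)


def make_web(community, links):
    """Build a PredationMatrix from a dense array or (resource, consumer) label pairs."""
    arr = np.zeros((community.size, community.size), dtype=np.int8)
    links = list(links) if not isinstance(links, np.ndarray) else links
    if isinstance(links, np.ndarray):
        arr[:] = links
    else:
        for res, con in links:
            arr[community.index_of(res), community.index_of(con)] = 1
    return PredationMatrix(community, arr)


@pytest.fixture
def chain3():
    """3-species chain A -> B -> C (B eats A, C eats B), masses 1 < 2 < 4."""
    comm = make_community([1.0, 2.0, 4.0])
    return comm, make_web(comm, [("A", "B"), ("B", "C")])


@pytest.fixture
def cycle4():
    """4-species directed cycle: each species eats the previous one."""
    comm = make_community([1.0, 2.0, 4.0, 8.0])
    return comm, make_web(comm, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
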