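"""Shared fixtures: the hand-checked 50-residue reference sequence and
small networks/tables used across the suite."""

import networkx as nx
import pytest

from protfun import ProteinRecord

# 50-residue reference sequence whose hydrophobicity translation and all
# C/T/D values are known by hand (see tests/test_ctd.py).
REF_SEQ = "MSDKPDMAEIEKFSKETIEQEKQAGESTQEKNPLPMLLPATDKSKLKKTE"
REF_TRANSLATION = "HNPPNPHNPHPPHNPPNHPPPPPNNPNNPPPPNHNHHHNNNPPNPHPPNP"


@pytest.fixture
def ref_record() -> ProteinRecord:
    return ProteinRecord(id="ref", sequence=REF_SEQ)


@pytest.fixture
def two_neighbor_net():
    """Query q with neighbours P1 (w 0.9, functions {1,7}) and
    P2 (w 0.4, functions {7,21})."""
    net = nx.Graph()
    net.add_edge("q", "P1", weight=0.9)
    net.add_edge("q", "P2", weight=0.4)
    ann = {"P1": frozenset({1, 7}), "P2": frozenset({7, 21})}
    return net, ann


@pytest.fixture
def triangle_net():
    """3-node triangle, all weights 1, everyone annotated {5}."""
    net = nx.Graph()
    for a, b in (("a", "b"), ("b", "c"), ("a", "c")):
        net.add_edge(a, b, weight=1.0)
    ann = {p: frozenset({5}) for p in "abc"}
    return net, ann
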