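import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from kpclique.core import build_graph
from kpclique.set_intersection import build_si_graph, make_set_system


@pytest.fixture
def triangle():
    """K_{1,1,1}: the smallest complete tripartite graph."""
    return build_graph([["a"], ["b"], ["c"]], [("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def ontology_system():
    """The worked 3-partite set-intersection example: universe {a..e},
    one part of subsets {a,b,d}, {a,d,e}, {c,d}, another of {b,e}, {b,c}."""
    return make_set_system(
        "abcde",
        [
            [("{a,b,d}", "abd"), ("{a,d,e}", "ade"), ("{c,d}", "cd")],
            [("{b,e}", "be"), ("{b,c}", "bc")],
        ],
    )


@pytest.fixture
def ontology_graph(ontology_system):
    return build_si_graph(ontology_system)


@pytest.fixture
def five_cycle_tripartite():
    """A 5-cycle arranged as a 3-partite graph; it is not a set-
    intersection graph for any choice of singleton part."""
    return build_graph(
        [["0", "1"], ["2"], ["3", "4"]],
        [("0", "2"), ("2", "4"), ("4", "1"), ("1", "3"), ("3", "0")],
    )
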