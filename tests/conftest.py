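import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from healthrec.graph import ConceptGraph
from healthrec.fixtures import FixtureSpec, generate_benchmark


@pytest.fixture
def cardio_graph() -> ConceptGraph:
    """Small hand-built graph around a myocardial-infarction concept."""
    g = ConceptGraph()
    g.add_edge("nstemi", "myocardial infarction", "REDIRECT", 1.0)
    g.add_edge("i21", "myocardial infarction", "CODE", 1.0)
    g.add_edge("myocardial infarction", "coronary disease", "ARTICLE", 1.0)
    g.add_edge("myocardial infarction", "heart diseases", "CATEGORY", 1.0)
    g.add_node("stemi")
    g.add_node("ecg")
    g.add_node("diabetes")
    g.add_node("diabetes mellitus")
    return g


@pytest.fixture(scope="session")
def benchmark_world():
    """The frozen seed-11 benchmark world used by end-to-end tests."""
    return generate_benchmark(FixtureSpec())
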