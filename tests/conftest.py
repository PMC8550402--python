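import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library():
    """Five consensi spanning DNA/LINE/LTR classes, deterministic."""
    from temelano.synthetic import generate_te_library

    return generate_te_library(5, {"DNA": 0.4, "LINE": 0.4, "LTR": 0.2}, seed=2)


@pytest.fixture(scope="session")
def planted_genome(small_library):
    """200 kb genome with 3 exact copies of each consensus, plus truth."""
    from temelano.synthetic import plant_insertions

    copies = {c.id: 3 for c in small_library}
    divs = {c.id: [0.0] for c in small_library}
    return plant_insertions(200_000, small_library, copies, divs, seed=3)
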