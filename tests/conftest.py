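import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from rponscan import (
    SimulationConfig,
    default_rponc_grammar,
    load_packaged_site_table,
    simulate_bundle,
)

#: The fixJ exemplar site from the packaged catalogue, used as the verbatim
#: planted site in closed-loop bundles.
EXEMPLAR_SITE = "TGGCGTGAATGCCGT"


@pytest.fixture(scope="session")
def grammar():
    return default_rponc_grammar()


@pytest.fixture(scope="session")
def table1():
    """The packaged 80-row published site catalogue."""
    return load_packaged_site_table()


def make_bundle(seed: int, **overrides):
    """A closed-loop bundle planting the exemplar site verbatim."""
    overrides.setdefault("site_sequences", (EXEMPLAR_SITE,))
    return simulate_bundle(SimulationConfig(seed=seed, **overrides))


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(seed=11)
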