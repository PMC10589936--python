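import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lig_run():
    """A small ligation-like simulated run shared across tests."""
    from nanoplex_qc import default_config, simulate_run

    return simulate_run(default_config(model="LIG", n_reads=2000, seed=11))


@pytest.fixture(scope="session")
def lig_synthesis(lig_run):
    from nanoplex_qc import build_synthesis

    return build_synthesis(
        lig_run.summary, lig_run.alignments, lig_run.config.barcode_map
    )
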