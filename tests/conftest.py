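import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_dataset():
    """Two-marker, 8-species dataset with a clear barcoding gap."""
    from barcodegap.simulate import MarkerSpec, SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_species=8,
        individuals_per_species=(2, 4),
        markers=[
            MarkerSpec("locA", 400, 1.0, 0),
            MarkerSpec("locB", 300, 0.5, 5),
        ],
        interspecific_depth=0.08,
        intraspecific_depth=0.004,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_matrix():
    from barcodegap.alignments import AlignedMatrix

    return AlignedMatrix(
        "toy",
        ["a1", "a2", "b1", "b2"],
        ["ACGTACGT", "ACGTACGA", "GCGTTCGT", "GCGTTCGA"],
    )
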