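import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lmiscreen as lm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_table():
    """2 ions x 3 samples raw table with a zero area."""
    return lm.PeakTable(
        ions=[lm.IonID(283.2018, 10.17), lm.IonID(505.3401, 11.03)],
        samples=["s1", "s2", "s3"],
        areas=np.array([[1000.0, 100.0, 0.0], [10.0, 1.0, 50.0]]),
        scale="raw",
        provenance={"RT tolerance": "0.01 min", "mass tolerance": "10.0 ppm"},
    )


@pytest.fixture
def two_group_manifest():
    return lm.CohortManifest({"s1": "PC", "s2": "PC", "s3": "control"})


def random_log_table(rng, n_ions, n_samples, prefix="S"):
    """Random log10-scale table with distinct ion coordinates."""
    ions = [lm.IonID(100.0 + 0.5 * k, 1.0 + 0.01 * k) for k in range(n_ions)]
    samples = [f"{prefix}{j}" for j in range(n_samples)]
    areas = rng.normal(4.0, 0.8, size=(n_ions, n_samples))
    return lm.PeakTable(ions, samples, areas, scale="log10")
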