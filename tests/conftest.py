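import numpy as np
import pytest

from retroscan.core import Interval
from retroscan.synthetic_data import InsertionSpec, SimulationConfig, build_reference


@pytest.fixture(scope="session")
def small_config():
    """A small, fast cohort configuration used across tests."""
    return SimulationConfig(
        n_samples=4,
        chrom_lengths={"chrA": 2_000_000, "chrB": 1_000_000, "chrC": 500_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def demo_specs(small_ref):
    """Planted truth shared by detection/recovery tests: three somatic events
    and one germline polymorphism."""
    return [
        InsertionSpec("som0", "chrB", 300_000, "somatic", ("S000",), vaf=0.5),
        InsertionSpec("som1", "chrB", 820_000, "somatic", ("S001",), vaf=0.3),
        InsertionSpec("som2", "chrC", 250_000, "somatic", ("S000",), vaf=1.0),
        InsertionSpec("germ0", "chrB", 600_000, "germline", ("S000", "S002")),
    ]
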