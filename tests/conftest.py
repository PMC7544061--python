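import pytest

from heatcanopy.io_schema import packaged_species_path, read_species_table
from heatcanopy.synthetic import CohortSpec, generate_tract_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic 500-tract cohort from the default three-factor model."""
    return generate_tract_cohort(CohortSpec(n_tracts=500, noise_sd=0.1, seed=42))


@pytest.fixture(scope="session")
def species_records():
    return read_species_table(packaged_species_path())
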