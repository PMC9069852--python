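import numpy as np
import pytest

from btmbkit.io import clinical_to_frame, plasma_to_frame, variants_to_frame, write_table
from btmbkit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient simulated cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=200, seed=42))


@pytest.fixture(scope="session")
def fixture_cohort_dir(tmp_path_factory):
    """A 400-patient cohort written as the three input TSVs."""
    cohort = simulate_cohort(SimulationConfig(n_patients=400, seed=42))
    d = tmp_path_factory.mktemp("cohort")
    write_table(clinical_to_frame(cohort.clinical), d / "clinical.tsv")
    write_table(variants_to_frame(cohort.variants), d / "variants.tsv")
    write_table(plasma_to_frame(cohort.plasma), d / "plasma.tsv")
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
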