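import pytest

from snpcoseg.experiments import reference_cohort_config
from snpcoseg.simulate import simulate_cohort, write_fixture


@pytest.fixture(scope="session")
def reference_cohort():
    """31-family synthetic cohort, 2 with misattributed paternity."""
    return simulate_cohort(reference_cohort_config(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(reference_cohort, tmp_path_factory):
    """The reference cohort written to disk (cohort.ped, panel.tsv, truth.json)."""
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(reference_cohort, d)
    return d
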