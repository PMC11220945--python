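import pytest

from mlpscore import build_toy_atlas
from mlpscore.diagnostics import ContingencyTable2x2
from mlpscore.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    return build_toy_atlas(voxel_size_mm=(1.0, 1.0, 1.0), seed=0)


@pytest.fixture(scope="session")
def published_table():
    """Severe-MLP vs unfavourable-outcome 2x2 table of the validation cohort."""
    return ContingencyTable2x2(tp=33, fp=2, fn=2, tn=10)


@pytest.fixture()
def validation_cohort():
    """47-patient cohort with the published MLP-by-outcome joint counts."""
    return simulate_cohort(CohortSpec(seed=11))
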