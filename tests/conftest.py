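import numpy as np
import pytest

from nodemetric.data import (
    Basin,
    CohortGroup,
    LymphNodeRecord,
    Reader,
    Sequence,
    TruthStatus,
)
from nodemetric.simulate import (
    default_config,
    generate_cohort,
    reference_structure_cohort,
)


def make_record(
    pid,
    nid,
    group=CohortGroup.SLN,
    truth=TruthStatus.BENIGN,
    reader=Reader.R1,
    adc_epi=None,
    **kw,
):
    adc = {}
    if adc_epi is not None:
        adc[Sequence.EPI] = adc_epi
    return LymphNodeRecord(
        patient_id=pid,
        node_id=nid,
        cohort_group=group,
        basin=kw.pop("basin", Basin.AXILLARY),
        truth_status=truth,
        reader=reader,
        adc=adc,
        **kw,
    )


@pytest.fixture(scope="session")
def structure_cohort():
    """Deterministic cohort replicating the study's set structure."""
    return reference_structure_cohort()


@pytest.fixture(scope="session")
def simulated_cohort():
    """One default synthetic cohort (both readers, panels, truth)."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
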