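import numpy as np
import pytest

from carrierscan import (
    CohortSpec,
    CountingUnit,
    GroupSpec,
    Role,
    generate_cohort,
)
from carrierscan import study


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged five-variant candidate panel."""
    return study.candidate_variant_panel()


@pytest.fixture(scope="session")
def study_cohort():
    """The packaged replication cohort (deterministic at seed 0)."""
    return generate_cohort(study.study_cohort_spec(seed=0))


@pytest.fixture()
def small_cohort():
    """A small two-group cohort for fast permutation / IO tests."""
    spec = CohortSpec(
        groups=(
            GroupSpec("cases", Role.CASE, CountingUnit.PARTICIPANT, 8, 8),
            GroupSpec("fams", Role.CASE, CountingUnit.FAMILY, 4, 6),
            GroupSpec("controls", Role.CONTROL, CountingUnit.PARTICIPANT, 12, 12),
        ),
        carrier_counts={"GENE:c.1A>G": {"cases": 2, "fams": 1, "controls": 1}},
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
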