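import pytest

from lpdscore import load_published_counts, generate
from lpdscore.cohort import Diagnosis
from lpdscore.scoring import score_cohort
from lpdscore.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def fx():
    return load_published_counts()


@pytest.fixture(scope="session")
def cohort125():
    """Default-size synthetic cohort (54/28/43), fixed seed."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def scored125(cohort125):
    return score_cohort(cohort125)


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for moment checks (5000 per group)."""
    cfg = GeneratorConfig(
        n_per_group={Diagnosis.RFH: 5000, Diagnosis.ALH: 5000, Diagnosis.MALTOMA: 5000}
    )
    return generate(cfg, seed=202)


@pytest.fixture(scope="session")
def big_scored(big_cohort):
    return score_cohort(big_cohort)
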