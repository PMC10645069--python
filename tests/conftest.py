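import numpy as np
import pytest

from repliscope.dataset import StatisticsReport, StudyPair
from repliscope.synth import GeneratorConfig, simulate_pairs


def make_pair(**overrides) -> StudyPair:
    """A fully populated valid pair; override any field."""
    base = dict(
        pair_id="p-001",
        class_year=2015,
        subfield="cognitive",
        open_data=True,
        open_materials=True,
        original_online=True,
        replication_online=True,
        stanford_affiliation=False,
        within_participants=False,
        single_vignette=False,
        n_trials=12,
        publication_year=2013,
        n_original=100,
        n_replication=80,
        closeness="close",
        subjective_score=0.75,
        same_direction=True,
        sensitivity_include=True,
        original_stats=StatisticsReport(
            test_type="means_between", m1=1.2, s1=1.0, n1=50, m2=0.7, s2=1.1, n2=50
        ),
        replication_stats=StatisticsReport(test_type="t_between", statistic=1.4, n1=40, n2=40),
    )
    base.update(overrides)
    return StudyPair(**base)


@pytest.fixture
def pair():
    return make_pair()


@pytest.fixture(scope="session")
def synthetic_pairs():
    """A deterministic mid-sized synthetic dataset shared across tests."""
    pairs, truth = simulate_pairs(GeneratorConfig(n_pairs=120, tau=0.1), seed=2024)
    return pairs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
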