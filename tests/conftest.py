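import pytest
from hypothesis import HealthCheck, settings

from motifspace import GeneratorConfig, fixture_paper_examples, sample_database

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_db():
    return fixture_paper_examples()


@pytest.fixture(scope="session")
def rb(paper_db):
    """The [LI].C.[DE] class, structure (2,20,1,20,2)."""
    return paper_db["RB_LIG_1"]


@pytest.fixture(scope="session")
def fiw(paper_db):
    """The [FI].W class, structure (2,20,1)."""
    return paper_db["TOY_FIW"]


@pytest.fixture(scope="session")
def synth_db():
    """60-class synthetic database with 10% planted duplicates."""
    return sample_database(
        GeneratorConfig(n_classes=60, duplicate_fraction=0.1, seed=7))
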