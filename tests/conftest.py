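import numpy as np
import pytest

from weibullcr.data_model import Dataset, SubjectRecord
from weibullcr.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Five hand-written records covering both causes and censoring."""
    rows = [
        (12.0, 1, "man", 55.0, 24.0, "II"),
        (30.0, 0, "woman", 48.0, 27.5, "I"),
        (7.5, 2, "man", 70.0, 22.0, "IV"),
        (90.0, 0, "woman", 39.0, 31.0, "III"),
        (48.0, 1, "woman", 61.0, 25.2, "III"),
    ]
    records = [
        SubjectRecord(time=t, event=e, sex=s, age=a, bmi=b, stage=st)
        for t, e, s, a, b, st in rows
    ]
    return Dataset(records=records, n_causes=2)


@pytest.fixture
def default_cohort():
    """A default-configuration synthetic cohort (n=372, seed 42)."""
    cfg = GeneratorConfig(seed=42)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def large_cohort():
    """A 2000-subject default-configuration cohort: enough cause-2 deaths
    (~4% of n) for both cause-specific fits to be well identified."""
    cfg = GeneratorConfig(n=2000, seed=42)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
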