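import pandas as pd
import pytest

from irdetect import SimulationConfig, build_feature_table, simulate_dataset

DEFAULT_SEED = 101


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset: 20 four-exon genes, planted IR + FP archetypes."""
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def feature_table(dataset) -> pd.DataFrame:
    return build_feature_table(
        dataset.treatment, dataset.control, dataset.catalog, dataset.genes
    )


@pytest.fixture(scope="session")
def truth_of(dataset) -> dict:
    return {t.intron_id: t.klass for t in dataset.truth}


def passing_record(**overrides) -> dict:
    """A feature record comfortably clearing every removal criterion."""
    rec = {
        "TNintron": 20.0, "TNexon": 50.0, "TNjunc": 5.0, "TN5ss": 8.0,
        "TN3ss": 8.0, "TNcoverage": 0.97, "TNexpression": 100.0,
        "CNintron": 2.0, "CNexon": 50.0, "CNjunc": 15.0, "CN5ss": 1.0,
        "CN3ss": 1.0, "CNcoverage": 0.2, "CNexpression": 100.0,
    }
    rec.update(overrides)
    return rec
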