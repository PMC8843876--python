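import numpy as np
import pytest
from hypothesis import settings

from smilesaug.augment import AugmentConfig, augment_dataset
from smilesaug.fixtures import SyntheticSpec, estradiol_fixture, generate_regression_set
from smilesaug.model import EncodedDataset
from smilesaug.preprocess import RawRecord, clean_dataset
from smilesaug.vectorize import encode, fit_encoding

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def estradiol():
    canonical, variants = estradiol_fixture()
    return canonical, variants


@pytest.fixture(scope="session")
def small_regression_frame():
    return generate_regression_set(
        SyntheticSpec(n_molecules=40, family="mixed", noise_sd=0.3, seed=5)
    )


@pytest.fixture(scope="session")
def clean_molecules(small_regression_frame):
    records = [
        RawRecord(i, row.smiles, {"property": row.property})
        for i, row in enumerate(small_regression_frame.itertuples(index=False))
    ]
    molecules, report = clean_dataset(records)
    assert report.n_output == len(records)
    return molecules


@pytest.fixture(scope="session")
def encoded_regression_dataset(clean_molecules):
    """Augmented + one-hot encoded version of the small regression set."""
    augmented = augment_dataset(clean_molecules, AugmentConfig(n_random=3, seed=5))
    spec = fit_encoding([r.smiles for r in augmented], extra_pad=5)
    samples = [
        encode(r.smiles, spec, r.parent_id, r.variant_index, r.labels)
        for r in augmented
    ]
    return EncodedDataset.from_samples(samples), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
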