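import numpy as np
import pytest

from semicorr import SemiCorrelationClassifier
from semicorr.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """120-compound planted-signal dataset, shared across tests."""
    return generate(GeneratorConfig(n_compounds=120, seed=42))


@pytest.fixture(scope="session")
def fitted_clf(small_dataset):
    """A quickly fitted classifier on the small dataset (capacity-limited,
    few epochs: enough structure for interface and consistency tests)."""
    clf = SemiCorrelationClassifier(T=3, n_epochs=8, random_state=0)
    clf.fit(small_dataset["smiles"].tolist(), small_dataset["label"].to_numpy())
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
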