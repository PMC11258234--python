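import numpy as np
import pytest

from molinverse.model import PropertyStructureVAE
from molinverse.synthetic import SyntheticDatasetSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic chemical space shared across the suite."""
    return make_dataset(SyntheticDatasetSpec(n=400, seed=11))


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """A model trained long enough to be usable (not converged to spec)."""
    _, X_tr, Y_tr = small_dataset.subset("train")
    model = PropertyStructureVAE(n_epochs=250, random_state=3)
    model.fit(X_tr, Y_tr)
    return model


@pytest.fixture()
def tiny_model():
    """A minimally fitted model for contract (not quality) checks."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 10))
    Y = rng.normal(size=(12, 4))
    model = PropertyStructureVAE(
        latent_dim=3, encoder_hidden=(8,), property_hidden=(6,),
        n_epochs=2, batch_size=4, random_state=0,
    )
    model.fit(X, Y)
    return model
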