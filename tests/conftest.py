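import numpy as np
import pytest

from odortl.chemio import load_table11_fixture, to_molecular_graph
from odortl.descriptor_gcn import DescriptorDataset, GCNConfig, split_dataset, train_gcn
from odortl.synthetic_data import SyntheticSpec, assign_descriptors, generate_molecules


@pytest.fixture(scope="session")
def fixture_rows():
    return load_table11_fixture()


@pytest.fixture(scope="session")
def trained_gcn_setup():
    """A descriptor GCN trained on a noise-free synthetic database.

    Labels are deterministic functions of substructure presence, so the
    network has clean signal to learn; shared across tests that need a
    trained model (learnability, embeddings, early-stopping contracts).
    """
    spec = SyntheticSpec(n_molecules=150, label_noise=0.0, seed=7)
    mols = generate_molecules(150, seed=7)
    ds = assign_descriptors(mols, spec)
    train, val, test = split_dataset(ds.records, (0.6, 0.2, 0.2), seed=7)
    config = GCNConfig(seed=7, max_epochs=80, patience=30)
    model, history = train_gcn(
        DescriptorDataset(train, ds.vocabulary), config,
        val_dataset=DescriptorDataset(val, ds.vocabulary),
    )
    return {
        "model": model,
        "history": history,
        "vocabulary": ds.vocabulary,
        "train": train,
        "val": val,
        "test": test,
        "config": config,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_graphs(fixture_rows):
    return [to_molecular_graph(r.molecule) for r in fixture_rows]
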