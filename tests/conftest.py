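import numpy as np
import pytest
from hypothesis import settings

from varfx import ensemble as ens
from varfx import features as feat
from varfx import homology as hom
from varfx import synthetic as syn
from varfx.io import VariantDataset, VariantRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_config():
    """Default study conditions: 2,000 variants, 60:40 effect:neutral, 5% noise."""
    return syn.SyntheticConfig(seed=7, n_variants=2000, noise_rate=0.05)


@pytest.fixture(scope="session")
def synth_dataset(synth_config):
    dataset, family_map = syn.generate_dataset(synth_config)
    return dataset, family_map


@pytest.fixture(scope="session")
def synth_folds(synth_dataset):
    dataset, _ = synth_dataset
    graph = hom.build_homology_graph(dataset.proteins)
    partition = hom.single_linkage_clusters(graph)
    return hom.assign_folds(partition, k=10, seed=0)


@pytest.fixture(scope="session")
def net_config():
    return ens.NetworkConfig(hidden_units=30, learning_rate=0.05, momentum=0.3,
                             max_repetitions=150, max_stagnant_rounds=15)


@pytest.fixture(scope="session")
def registry():
    return feat.default_registry()


@pytest.fixture(scope="session")
def trained_ensemble(synth_dataset, synth_folds, net_config, registry):
    """Ten-network ensemble trained on the planted-signal dataset."""
    dataset, _ = synth_dataset
    descriptors = feat.noali_descriptors()
    return ens.train_ensemble(dataset, synth_folds, descriptors, registry,
                              grid=net_config, seed=3)


@pytest.fixture(scope="session")
def null_ensemble(synth_dataset, synth_folds, net_config, registry):
    """Same training run with labels randomly permuted across variants."""
    dataset, _ = synth_dataset
    rng = np.random.default_rng(11)
    labels = [v.label for v in dataset.variants]
    perm = rng.permutation(len(labels))
    variants = [
        VariantRecord(v.protein_id, v.position, v.wt_aa, v.var_aa,
                      label=labels[i], source=v.source)
        for v, i in zip(dataset.variants, perm)
    ]
    shuffled = VariantDataset(proteins=dataset.proteins, variants=variants)
    descriptors = feat.noali_descriptors()
    return ens.train_ensemble(shuffled, synth_folds, descriptors, registry,
                              grid=net_config, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap 600-variant dataset for unit-scale training tests."""
    config = syn.SyntheticConfig(seed=5, n_variants=600)
    dataset, family_map = syn.generate_dataset(config)
    graph = hom.build_homology_graph(dataset.proteins)
    folds = hom.assign_folds(hom.single_linkage_clusters(graph), k=10, seed=0)
    return dataset, folds
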