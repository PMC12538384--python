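import warnings

import numpy as np
import pytest

from qtaimnet.density import AtomSite, ModelDensity
from qtaimnet.graphs import FeatureSchema
from qtaimnet.pipeline import featurize_complexes, standardize_records
from qtaimnet.synthetic import (
    assign_labels,
    build_topologies,
    default_label_rule,
    generate_dataset,
)
from qtaimnet.topology import build_topology


def simple_atom(index=0, pos=(0.0, 0.0, 0.0), c=1.0, zeta=1.0, element="C"):
    return AtomSite(index=index, element=element, position=np.asarray(pos, float),
                    shells=((c, zeta),))


@pytest.fixture
def diatomic():
    """Symmetric homonuclear diatomic, separation 4 bohr, single unit shell."""
    atoms = [simple_atom(0, (0, 0, 0)), simple_atom(1, (4.0, 0, 0))]
    return atoms


@pytest.fixture
def diatomic_model(diatomic):
    return ModelDensity(diatomic)


@pytest.fixture
def triatomic_ring():
    """Equilateral homonuclear triangle with 4 bohr sides."""
    d = 4.0
    pts = [(0, 0, 0), (d, 0, 0), (d / 2, d * np.sqrt(3) / 2, 0)]
    return [simple_atom(i, p) for i, p in enumerate(pts)]


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 60-complex synthetic dataset with topologies and labels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        complexes = generate_dataset(60, seed=11, n_ligands_range=(3, 5))
        topologies = build_topologies(complexes)
    labels = assign_labels(complexes, topologies, default_label_rule(), seed=11)
    return complexes, topologies, labels


@pytest.fixture(scope="session")
def small_records(small_dataset):
    """Standardized QTAIM-on graph records for the shared dataset."""
    complexes, topologies, labels = small_dataset
    schema = FeatureSchema()
    records = featurize_complexes(complexes, topologies, labels, schema)
    train_ids = [r.id for r in records[:45]]
    records_std, stats = standardize_records(records, train_ids, schema)
    return records_std, stats, schema
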