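import numpy as np
import pytest

from dilimine.simulate import (
    SyntheticSpec,
    generate_compound_set,
    generate_feature_matrix,
)
from dilimine.features import fingerprint_matrix
from dilimine.similarity import cluster, similarity_matrix


@pytest.fixture(scope="session")
def study_spec():
    """The default synthetic study conditions (200+200 compounds)."""
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def study_compounds(study_spec):
    return generate_compound_set(study_spec)


@pytest.fixture(scope="session")
def study_labels(study_compounds):
    return np.where(study_compounds["dili_class"].to_numpy() == "vMost", 1, 0)


@pytest.fixture(scope="session")
def study_features(study_spec, study_labels):
    return generate_feature_matrix(study_spec, study_labels).to_numpy()


@pytest.fixture(scope="session")
def study_fps(study_compounds):
    return fingerprint_matrix(
        study_compounds["smiles"].tolist(),
        study_compounds["compound_id"].tolist(),
    ).values


@pytest.fixture(scope="session")
def study_clusters(study_fps):
    return cluster(similarity_matrix(study_fps))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced recipe for fast unit-level checks."""
    return SyntheticSpec(
        n_pos=40,
        n_neg=40,
        n_target_features=30,
        planted_features=tuple((j, 0.4) for j in range(10)),
        seed=11,
    )
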