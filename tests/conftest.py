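import numpy as np
import pytest

from manifoldgeom import ActivityDataset, ConceptSpec, ManifoldSpec
from manifoldgeom.synthetic import random_orthonormal_basis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_dataset(
    rng,
    n_concepts=2,
    ambient_dim=20,
    n_exemplars=60,
    separation=2.0,
    scale=1.0,
):
    """Isotropic Gaussian concept clouds with centres ``separation`` apart."""
    blocks, labels = [], []
    for i in range(n_concepts):
        center = np.zeros(ambient_dim)
        if i:
            center[i - 1] = separation
        X = center + scale * rng.standard_normal((n_exemplars, ambient_dim))
        blocks.append(X)
        labels.append(np.repeat(f"c{i}", n_exemplars))
    return ActivityDataset(np.vstack(blocks), np.concatenate(labels))


def make_lowrank_spec(
    rng,
    n_concepts=2,
    ambient_dim=40,
    intrinsic_dim=6,
    separation=1.0,
    n_exemplars=200,
):
    """Anisotropic low-rank spec with explicit (materialized) bases."""
    concepts = {}
    lam = np.exp(-np.arange(intrinsic_dim) / 3.0)
    lam = lam / lam.sum()
    for i in range(n_concepts):
        center = rng.standard_normal(ambient_dim)
        center *= separation / np.linalg.norm(center)
        basis = random_orthonormal_basis(ambient_dim, intrinsic_dim, rng)
        concepts[f"c{i}"] = ConceptSpec(
            center=center, spectrum=lam.copy(), basis=basis, n_exemplars=n_exemplars
        )
    return ManifoldSpec(ambient_dim=ambient_dim, concepts=concepts)


@pytest.fixture
def gaussian_dataset(rng):
    return make_gaussian_dataset(rng)


@pytest.fixture
def lowrank_spec(rng):
    return make_lowrank_spec(rng)
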