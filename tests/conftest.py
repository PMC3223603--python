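import numpy as np
import pytest

from combotan.molecules import Atom, Conformer, FeaturePoint
from combotan.synthetic import GeneratorConfig, random_conformer, sample_population
from combotan.transforms import RigidTransform


def make_conformer(cid, positions, elements=None, features=()):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    elements = elements or ["C"] * len(positions)
    atoms = [Atom(e, p) for e, p in zip(elements, positions)]
    feats = [FeaturePoint.from_members(ft, atoms, members) for ft, members in features]
    return Conformer(cid=cid, atoms=atoms, features=feats)


def random_rigid(rng, scale=5.0):
    w = rng.normal(size=3)
    t = rng.normal(scale=scale, size=3)
    return RigidTransform.from_rotvec(w, t)


@pytest.fixture(scope="session")
def population():
    """Small synthetic compound population shared across tests."""
    return sample_population(GeneratorConfig(seed=11, n_compounds=30))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_conformers():
    """A handful of small (<=8 atom) conformers for quadrature comparisons."""
    rng = np.random.default_rng(7)
    cfg = GeneratorConfig(seed=7)
    return [random_conformer(rng, int(n), cid=100 + i, config=cfg)
            for i, n in enumerate(rng.integers(2, 9, size=8))]
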