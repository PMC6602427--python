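"""Shared fixtures: toy complexes, independent oracles, a small trained model."""

from pathlib import Path

import numpy as np
import pytest

from ppiddg import model as mdl
from ppiddg import structure_io as sio
from ppiddg.pipeline import features_for_mutations

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def toy_complex() -> sio.Structure:
    """Two 6-residue chains, 4 A apart, mixed sequence at the interface."""
    return sio.make_toy_complex(6, 4.0, seed=42,
                                sequence_a="AFKDSA", sequence_b="AWENTA")


@pytest.fixture(scope="session")
def poly_ala_complex() -> sio.Structure:
    return sio.make_toy_complex(5, 4.0, seed=42)


def brute_force_signature(env, cutoffs):
    """Independent all-pairs signature oracle: direct cumulative counts.

    For each cutoff, counts every atom pair with distance <= cutoff once
    per unordered label pair it realises (no binning + cumsum shortcut).
    """
    import itertools

    from ppiddg.signatures import PAIR_CLASSES

    idx = {frozenset(p) if p[0] != p[1] else frozenset([p[0]]): i
           for i, p in enumerate(PAIR_CLASSES)}
    counts = np.zeros((len(PAIR_CLASSES), len(cutoffs)), dtype=np.int64)
    for k, cut in enumerate(cutoffs):
        for a, b in itertools.combinations(env.atoms, 2):
            if np.linalg.norm(a.coord - b.coord) > cut:
                continue
            pairs = {frozenset([la, lb]) for la in a.labels for lb in b.labels}
            for p in pairs:
                counts[idx[p], k] += 1
    return counts


def random_environment(rng, n_atoms, box=12.0):
    """Random pharmacophore-labeled atom cloud for oracle comparisons."""
    from ppiddg import data as tables
    from ppiddg.signatures import AtomEnvironment, LabeledAtom

    atoms = []
    for _ in range(n_atoms):
        coord = rng.uniform(-box, box, size=3)
        k = rng.integers(1, 4)
        labels = frozenset(rng.choice(tables.PHARMACOPHORES, size=k,
                                      replace=False).tolist())
        atoms.append(LabeledAtom(coord, "C", labels))
    return AtomEnvironment(center=np.zeros(3), atoms=atoms, radius=box * 2)


@pytest.fixture(scope="session")
def toy_training(toy_complex):
    """Feature table + synthetic targets for a handful of toy mutations."""
    muts = [(sio.ResidueRef("A", i), aa)
            for i in (2, 3, 4) for aa in ("G", "W", "E", "L")]
    X = features_for_mutations(toy_complex, muts)
    rng = np.random.default_rng(0)
    y = rng.normal(scale=1.5, size=len(X))
    return X, y


@pytest.fixture(scope="session")
def toy_model(toy_training):
    X, y = toy_training
    return mdl.train(X, y, config={"n_estimators": 30}, seed=7)
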