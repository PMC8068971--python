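import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_mna importable

from posmna.chemgraph import MolecularGraph, flag_ring_atoms, prepare
from posmna.descriptors import MnaDescriptorSet, posmna_set
from posmna.model import PairRecord, TrainingTable, pair_key
from posmna.synthdata import (
    WARFARIN_SMILES,
    NAPROXEN_SMILES,
    generate_library,
    library_graphs,
)


@pytest.fixture(scope="session")
def warfarin():
    return prepare(WARFARIN_SMILES, "warfarin")


@pytest.fixture(scope="session")
def naproxen():
    return prepare(NAPROXEN_SMILES, "naproxen")


@pytest.fixture(scope="session")
def small_library():
    """A seeded scaffold library large enough for 200-pair tables."""
    records = generate_library(5, 480)
    return records, library_graphs(records)


def random_graph(rng, n_max=20):
    """Random connected molecule-like graph: a tree plus a few extra edges.

    Heavy atoms from the organic subset; hydrogens only as leaves.
    """
    n = int(rng.integers(2, n_max + 1))
    heavy_elements = ["C", "N", "O", "S", "P", "Cl", "Br", "F"]
    elements = [str(rng.choice(heavy_elements)) for _ in range(n)]
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    n_extra = int(rng.integers(0, 3))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        i, j = int(i), int(j)
        if i != j and (min(i, j), max(i, j)) not in [
            (min(a, b), max(a, b)) for a, b in edges
        ]:
            edges.append((min(i, j), max(i, j)))
    # sprinkle hydrogens on low-degree vertices
    degree = {i: 0 for i in range(n)}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    for i in range(n):
        for _ in range(int(rng.integers(0, max(1, 4 - degree[i])))):
            h = len(elements)
            elements.append("H")
            edges.append((i, h))
    g = MolecularGraph.from_edges(elements, edges)
    return flag_ring_atoms(g), elements, edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def build_table(rows, graphs, activities):
    """Resolve (id_a, id_b, activity) rows into a TrainingTable."""
    from posmna.descriptors import mna_set

    mna = {}
    labels = {}
    for a, b, act in rows:
        labels.setdefault(pair_key(a, b), set()).add(act)
        for mid in (a, b):
            if mid not in mna:
                mna[mid] = mna_set(graphs[mid])
    pairs = [
        PairRecord(k, frozenset(v), posmna_set(mna[k[0]], mna[k[1]]).descriptors)
        for k, v in sorted(labels.items())
    ]
    return TrainingTable(pairs=pairs, activities=tuple(activities))


def abstract_table(rng, n_pairs=30, n_desc=40, activities=("A", "B", "C")):
    """Training table over abstract descriptor strings (no chemistry)."""
    vocab = [f"d{i:02d}" for i in range(n_desc)]
    pairs = []
    while True:
        pairs.clear()
        for i in range(n_pairs):
            size = int(rng.integers(3, 10))
            D = frozenset(str(d) for d in rng.choice(vocab, size=size, replace=False))
            labels = {str(rng.choice(activities))}
            if rng.random() < 0.3:
                labels.add(str(rng.choice(activities)))
            pairs.append(PairRecord((f"m{i:03d}", f"n{i:03d}"), frozenset(labels), D))
        counts = {a: sum(a in p.labels for p in pairs) for a in activities}
        # every activity needs >=2 positives and >=2 negatives so that
        # leave-one-out retraining stays well defined
        if all(2 <= c <= n_pairs - 2 for c in counts.values()):
            return TrainingTable(pairs=pairs, activities=tuple(activities))
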