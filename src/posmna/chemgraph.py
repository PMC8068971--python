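"""Hydrogen-complete molecular graphs with ring-membership flags.

The neighborhood descriptors used throughout this package consume exactly
three pieces of structural information per atom: its element symbol, whether
it lies on a ring, and its bonded neighbors (hydrogens made explicit).  Bond
orders, charges, isotopes and stereochemistry are read by the parser but do
not enter the descriptor substrate.  This module builds that substrate from
SMILES or SDF input via RDKit and exposes the small graph algebra the
descriptor generator needs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger

from .errors import MultiComponentError, StructureParseError

RDLogger.DisableLog("rdApp.*")  # diagnostics are surfaced as exceptions instead


@dataclass(frozen=True)
class Atom:
    """One atom of a :class:`MolecularGraph`."""

    index: int
    element: str
    in_ring: bool = False
    is_hydrogen: bool = False


@dataclass(frozen=True)
class MolecularGraph:
    """An undirected molecular graph.

    ``adjacency[i]`` is the sorted tuple of neighbor indices of atom ``i``;
    the relation is symmetric and irreflexive.  ``implicit_h[i]`` counts
    hydrogens still implicit on atom ``i`` (zero after
    :func:`add_explicit_hydrogens`).
    """

    atoms: tuple[Atom, ...]
    adjacency: tuple[tuple[int, ...], ...]
    implicit_h: tuple[int, ...]
    molecule_id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if j == i:
                    raise ValueError(f"self-loop on atom {i}")
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric adjacency {i}-{j}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(a.index for a in self.atoms if not a.is_hydrogen)

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    def components(self) -> list[list[int]]:
        """Connected components as sorted lists of atom indices."""
        seen: set[int] = set()
        out: list[list[int]] = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            comp = []
            queue = deque([start])
            seen.add(start)
            while queue:
                v = queue.popleft()
                comp.append(v)
                for w in self.adjacency[v]:
                    if w not in seen:
                        seen.add(w)
                        queue.append(w)
            out.append(sorted(comp))
        return out

    @property
    def component_count(self) -> int:
        return len(self.components())

    @classmethod
    def from_edges(
        cls,
        elements: list[str],
        edges: list[tuple[int, int]],
        molecule_id: str | None = None,
    ) -> "MolecularGraph":
        """Build a graph directly from element symbols and an edge list.

        Intended for synthetic/abstract graphs; no valence model is applied
        (``implicit_h`` is all zero) and ring flags start unset — call
        :func:`flag_ring_atoms` afterwards.
        """
        nbrs: list[set[int]] = [set() for _ in elements]
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            nbrs[i].add(j)
            nbrs[j].add(i)
        atoms = tuple(
            Atom(i, el, in_ring=False, is_hydrogen=(el == "H"))
            for i, el in enumerate(elements)
        )
        return cls(
            atoms=atoms,
            adjacency=tuple(tuple(sorted(s)) for s in nbrs),
            implicit_h=tuple(0 for _ in elements),
            molecule_id=molecule_id,
        )


def _graph_from_rdkit(mol: Chem.Mol, molecule_id: str | None) -> MolecularGraph:
    atoms = []
    implicit = []
    nbrs: list[set[int]] = [set() for _ in range(mol.GetNumAtoms())]
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        atoms.append(
            Atom(i, atom.GetSymbol(), in_ring=False, is_hydrogen=atom.GetAtomicNum() == 1)
        )
        implicit.append(atom.GetTotalNumHs())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        nbrs[i].add(j)
        nbrs[j].add(i)
    g = MolecularGraph(
        atoms=tuple(atoms),
        adjacency=tuple(tuple(sorted(s)) for s in nbrs),
        implicit_h=tuple(implicit),
        molecule_id=molecule_id,
    )
    return flag_ring_atoms(g)


def parse_structure(text: str, record_id: str | None = None) -> MolecularGraph:
    """Parse one SMILES string or one V2000 SDF/Mol record.

    Aromatic perception is resolved to ring membership; stereochemical
    annotations are accepted by the parser but deliberately discarded, and
    bond orders are not retained beyond hydrogen counting.
    """
    if not text.strip():
        raise StructureParseError("empty structure record", record_id)
    if "\n" in text or "V2000" in text:
        # mol blocks are positional: pass them through untrimmed
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
        kind = "SDF record"
    else:
        text = text.strip()
        mol = Chem.MolFromSmiles(text, sanitize=True)
        kind = f"SMILES {text!r}"
    if mol is None:
        raise StructureParseError(f"could not parse {kind}", record_id)
    if mol.GetNumAtoms() == 0:
        raise StructureParseError(f"{kind} contains no atoms", record_id)
    return _graph_from_rdkit(mol, record_id)


def add_explicit_hydrogens(g: MolecularGraph) -> MolecularGraph:
    """Materialize every implicit hydrogen as an explicit degree-1 atom.

    Idempotent: a hydrogen-complete graph is returned unchanged.
    """
    if not any(g.implicit_h):
        return g
    atoms = list(g.atoms)
    adjacency = [set(n) for n in g.adjacency]
    for i, count in enumerate(g.implicit_h):
        for _ in range(count):
            h = len(atoms)
            atoms.append(Atom(h, "H", in_ring=False, is_hydrogen=True))
            adjacency.append({i})
            adjacency[i].add(h)
    return MolecularGraph(
        atoms=tuple(atoms),
        adjacency=tuple(tuple(sorted(s)) for s in adjacency),
        implicit_h=tuple(0 for _ in atoms),
        molecule_id=g.molecule_id,
    )


def _non_bridge_atoms(g: MolecularGraph) -> set[int]:
    """Indices of atoms incident to at least one non-bridge edge.

    An edge lies on a cycle iff it is not a bridge, and an atom lies on a
    cycle iff one of its edges does.  Bridges are found with an iterative
    low-link DFS.
    """
    n = g.n_atoms
    disc = [-1] * n
    low = [0] * n
    ring_atoms: set[int] = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        # stack entries: (vertex, parent, iterator over neighbors)
        stack = [(root, -1, iter(g.adjacency[root]))]
        disc[root] = low[root] = timer
        timer += 1
        parent_edge_used = [False] * n  # one tree edge back to parent allowed
        while stack:
            v, parent, it = stack[-1]
            advanced = False
            for w in it:
                if w == parent and not parent_edge_used[v]:
                    parent_edge_used[v] = True  # skip the tree edge once
                    continue
                if disc[w] == -1:
                    disc[w] = low[w] = timer
                    timer += 1
                    stack.append((w, v, iter(g.adjacency[w])))
                    advanced = True
                    break
                low[v] = min(low[v], disc[w])
                if disc[w] < disc[v]:  # back edge: v..w path is a cycle
                    ring_atoms.add(v)
                    ring_atoms.add(w)
            if not advanced:
                stack.pop()
                if parent != -1:
                    low[parent] = min(low[parent], low[v])
                    if low[v] <= disc[parent]:
                        # edge (parent, v) is not a bridge
                        ring_atoms.add(parent)
                        ring_atoms.add(v)
        # atoms whose low-link reaches above them are inside some cycle
    return ring_atoms


def flag_ring_atoms(g: MolecularGraph) -> MolecularGraph:
    """Set ``in_ring`` exactly for atoms lying on at least one cycle.

    Ring membership is binary and cycle-based (not dependent on a smallest
    set of smallest rings); explicit hydrogens can never be in a ring.
    """
    on_cycle = _non_bridge_atoms(g)
    atoms = tuple(
        replace(a, in_ring=(a.index in on_cycle and not a.is_hydrogen))
        for a in g.atoms
    )
    return MolecularGraph(
        atoms=atoms,
        adjacency=g.adjacency,
        implicit_h=g.implicit_h,
        molecule_id=g.molecule_id,
    )


def require_single_component(
    g: MolecularGraph, strip_salts: bool = False
) -> MolecularGraph:
    """Reject multi-component structures, or keep the largest fragment.

    Training and prediction operate on single-component organic compounds;
    with ``strip_salts`` the component with the most heavy atoms is retained
    (a tie between the largest components is an error).
    """
    comps = g.components()
    if len(comps) == 1:
        return g
    heavy_sizes = [
        sum(1 for i in comp if not g.atoms[i].is_hydrogen) for comp in comps
    ]
    if not strip_salts:
        raise MultiComponentError(g.molecule_id, sorted(heavy_sizes, reverse=True))
    best = max(heavy_sizes)
    winners = [c for c, s in zip(comps, heavy_sizes) if s == best]
    if len(winners) > 1:
        raise MultiComponentError(g.molecule_id, sorted(heavy_sizes, reverse=True))
    keep = winners[0]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = tuple(
        replace(g.atoms[old], index=remap[old]) for old in keep
    )
    adjacency = tuple(
        tuple(sorted(remap[w] for w in g.adjacency[old])) for old in keep
    )
    implicit = tuple(g.implicit_h[old] for old in keep)
    return MolecularGraph(atoms, adjacency, implicit, molecule_id=g.molecule_id)


def prepare(
    text: str, record_id: str | None = None, strip_salts: bool = False
) -> MolecularGraph:
    """Full pipeline: parse, enforce single component, add hydrogens, flag rings."""
    g = parse_structure(text, record_id)
    g = require_single_component(g, strip_salts=strip_salts)
    g = add_explicit_hydrogens(g)
    return flag_ring_atoms(g)
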