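"""Multilevel Neighborhoods of Atoms (MNA) and pair (PoSMNA) descriptors.

An MNA descriptor of level *k* describes an atom by its element label and,
recursively, the level *k−1* descriptors of all bonded neighbors (hydrogens
included).  The label is the element symbol, prefixed by ``-`` when the atom
is acyclic::

    D0 := ['-'] ELEMENT
    Dk := ['-'] ELEMENT '(' <collate-sorted concatenation of neighbors' D(k-1)> ')'

A molecule is represented by the set of unique level-2 descriptors of its
heavy atoms.  A pair of molecules is represented by the PoSMNA set: the
direct product of the two molecules' MNA/2 sets, each cross term written as
the two component strings in canonical (collation) order joined by a single
space, so the pair descriptor is invariant under swapping the molecules.

The collation is character-wise under a fixed alphabet ranking in which
``(`` < ``)`` < element letters (ASCII order) < ``-``: the acyclic mark
sorts *after* all letters.  This ordering simultaneously places ``C(CCC)``
before ``C(CC-H)`` and every ring-atom descriptor before every ``-``-prefixed
acyclic-atom descriptor, which is how printed descriptor lists are arranged.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

from sklearn.base import BaseEstimator, TransformerMixin

from .chemgraph import MolecularGraph, prepare
from .errors import DescriptorError

DEFAULT_LEVEL = 2

# Collation: remap each character so that ordinary string comparison of the
# translated text realizes '(' < ')' < letters < '-'.  The pair separator
# (space) is ranked lowest; for well-formed same-level descriptors it can
# never decide a comparison (balanced parentheses rule out proper prefixes).
_COLLATE_TABLE = str.maketrans(
    {" ": "\x01", "(": "\x02", ")": "\x03", "-": "\x7f"}
)


def collation_key(s: str) -> str:
    """Sort key realizing the descriptor collation via plain string order."""
    return s.translate(_COLLATE_TABLE)


def collate(s1: str, s2: str) -> int:
    """Three-way comparison under the descriptor collation: -1, 0 or +1."""
    k1, k2 = collation_key(s1), collation_key(s2)
    return (k1 > k2) - (k1 < k2)


def descriptor_sorted(strings) -> list[str]:
    """Sort descriptor strings by the collation (stable)."""
    return sorted(strings, key=collation_key)


@dataclass(frozen=True)
class MnaDescriptorSet:
    """Unique canonical MNA strings of one molecule's heavy-atom centers."""

    molecule_id: str | None
    level: int
    descriptors: frozenset[str]

    def sorted(self) -> list[str]:
        return descriptor_sorted(self.descriptors)


@dataclass(frozen=True)
class PairDescriptorSet:
    """Unique PoSMNA strings of an unordered molecule pair."""

    pair_id: tuple[str | None, str | None]
    level: int
    descriptors: frozenset[str]

    def sorted(self) -> list[str]:
        return descriptor_sorted(self.descriptors)


def _atom_label(g: MolecularGraph, i: int) -> str:
    a = g.atoms[i]
    return a.element if a.in_ring else "-" + a.element


def _levels(g: MolecularGraph, level: int) -> list[str]:
    """Level-``level`` descriptor string for every atom of ``g``."""
    labels = [_atom_label(g, i) for i in range(g.n_atoms)]
    current = labels
    for _ in range(level):
        nxt = []
        for i in range(g.n_atoms):
            inner = "".join(
                sorted((current[j] for j in g.adjacency[i]), key=collation_key)
            )
            nxt.append(labels[i] + "(" + inner + ")")
        current = nxt
    return current


def mna_descriptor(g: MolecularGraph, center: int, level: int = DEFAULT_LEVEL) -> str:
    """Canonical MNA descriptor of ``center`` at the given level."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if not 0 <= center < g.n_atoms:
        raise DescriptorError(f"atom index {center} out of range")
    return _levels(g, level)[center]


def mna_set(g: MolecularGraph, level: int = DEFAULT_LEVEL) -> MnaDescriptorSet:
    """Unique MNA descriptors over all heavy-atom centers of ``g``.

    The graph must be hydrogen-complete and ring-flagged (see
    :func:`posmna.chemgraph.prepare`); hydrogens contribute to neighborhoods
    but are not descriptor centers.
    """
    heavy = g.heavy_indices
    if not heavy:
        raise DescriptorError(
            f"molecule {g.molecule_id!r} has no heavy atoms"
        )
    if any(g.implicit_h):
        raise DescriptorError(
            f"molecule {g.molecule_id!r} still has implicit hydrogens; "
            "call add_explicit_hydrogens first"
        )
    texts = _levels(g, level)
    return MnaDescriptorSet(
        molecule_id=g.molecule_id,
        level=level,
        descriptors=frozenset(texts[i] for i in heavy),
    )


def pair_text(x: str, y: str) -> str:
    """Canonical PoSMNA string for one cross term: components in collation order."""
    if collate(x, y) <= 0:
        return x + " " + y
    return y + " " + x


def posmna_set(a: MnaDescriptorSet, b: MnaDescriptorSet) -> PairDescriptorSet:
    """Direct product of two MNA sets, as canonical unordered pair strings.

    Symmetric in its arguments; the result size is at most ``|a|·|b|``
    (identical cross terms, including self-pairs ``"x x"``, collapse).
    """
    if a.level != b.level:
        raise DescriptorError(
            f"level mismatch: {a.level} vs {b.level}"
        )
    if not a.descriptors or not b.descriptors:
        raise DescriptorError("cannot build PoSMNA set from an empty MNA set")
    out = frozenset(pair_text(x, y) for x in a.descriptors for y in b.descriptors)
    return PairDescriptorSet(
        pair_id=(a.molecule_id, b.molecule_id), level=a.level, descriptors=out
    )


def pair_descriptors(
    ga: MolecularGraph, gb: MolecularGraph, level: int = DEFAULT_LEVEL
) -> PairDescriptorSet:
    """PoSMNA set straight from two prepared molecular graphs."""
    return posmna_set(mna_set(ga, level), mna_set(gb, level))


class PoSMNAEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping molecule pairs to PoSMNA descriptor sets.

    Each input sample is a pair ``(mol_a, mol_b)`` where the items are
    prepared :class:`~posmna.chemgraph.MolecularGraph` objects or SMILES
    strings.  ``transform`` returns a list of ``frozenset[str]``, the form
    consumed by :class:`~posmna.model.PairInteractionClassifier`.

    Parameters
    ----------
    level : int, default 2
        MNA recursion depth.
    strip_salts : bool, default False
        When parsing SMILES, keep the largest component of multi-component
        inputs instead of rejecting them.
    """

    def __init__(self, level: int = DEFAULT_LEVEL, strip_salts: bool = False):
        self.level = level
        self.strip_salts = strip_salts

    def fit(self, X=None, y=None):
        self.n_features_in_ = 2
        return self

    @functools.lru_cache(maxsize=4096)
    def _mna_from_smiles(self, smiles: str) -> MnaDescriptorSet:
        g = prepare(smiles, strip_salts=self.strip_salts)
        return mna_set(g, self.level)

    def _as_mna(self, mol) -> MnaDescriptorSet:
        if isinstance(mol, MolecularGraph):
            return mna_set(mol, self.level)
        return self._mna_from_smiles(mol)

    def transform(self, X) -> list[frozenset[str]]:
        out = []
        for mol_a, mol_b in X:
            out.append(
                posmna_set(self._as_mna(mol_a), self._as_mna(mol_b)).descriptors
            )
        return out
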