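"""Seeded generator of molecule libraries and labeled DDI pair tables.

The real training data behind CYP-mediated interaction models (curated
drug-pair tables) cannot be redistributed, so this module fabricates a
stand-in with *planted, recoverable* structure:

* a molecule library built by decorating ~40 curated drug-like scaffolds
  (warfarin and naproxen are always present verbatim) with small
  substituents at enumerated ring positions — chemical validity is
  guaranteed by construction, no valence repair needed;
* a pair table whose activity labels are planted functions of substructure
  co-occurrence: each of the seven CYP classes is tied to a pair of
  scaffold-specific MNA/2 descriptors, one required in each molecule of the
  pair (order-free, matching the unordered-pair model), with optional
  symmetric label noise;
* a class-imbalance profile mirroring a realistic interaction corpus where
  one class (CYP3A4) dominates with roughly 69% of all pairs.

Everything is deterministic under a single seed: the same seed yields
byte-identical libraries and tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chemgraph import MolecularGraph, prepare
from .descriptors import (
    DEFAULT_LEVEL,
    MnaDescriptorSet,
    collation_key,
    mna_set,
)
from .errors import PosmnaError
from .model import CYP_ACTIVITIES, pair_key

WARFARIN_SMILES = "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"
NAPROXEN_SMILES = "COc1ccc2cc(C(C)C(=O)O)ccc2c1"

#: Substituents enumerated at each decoration site ("" = hydrogen).
DECORATIONS = (
    "",
    "(C)",
    "(CC)",
    "(O)",
    "(OC)",
    "(F)",
    "(Cl)",
    "(Br)",
    "(I)",
    "(N)",
    "(C#N)",
    "(C(F)(F)F)",
)


@dataclass(frozen=True)
class Scaffold:
    name: str
    template: str  # SMILES with {R1}/{R2} decoration sites

    def realize(self, r1: str, r2: str) -> str:
        return self.template.format(R1=r1, R2=r2)


# The first 14 scaffolds are reserved for the planted interaction rules
# (two disjoint scaffold families per CYP class, in CYP_ACTIVITIES order).
SCAFFOLDS: tuple[Scaffold, ...] = (
    Scaffold("indole", "[nH]1ccc2cc{R1}c{R2}cc12"),
    Scaffold("benzofuran", "o1ccc2cc{R1}c{R2}cc12"),
    Scaffold("benzothiophene", "s1ccc2cc{R1}c{R2}cc12"),
    Scaffold("benzimidazole", "[nH]1cnc2cc{R1}c{R2}cc12"),
    Scaffold("benzoxazole", "o1cnc2cc{R1}c{R2}cc12"),
    Scaffold("benzothiazole", "s1cnc2cc{R1}c{R2}cc12"),
    Scaffold("indazole", "[nH]1ncc2cc{R1}c{R2}cc12"),
    Scaffold("cinnoline", "n1ncc2cc{R1}c{R2}cc2c1"),
    Scaffold("isoquinoline", "n1ccc2cc{R1}c{R2}cc2c1"),
    Scaffold("quinazoline", "n1cnc2cc{R1}c{R2}cc2c1"),
    Scaffold("quinoxaline", "n1ccnc2cc{R1}c{R2}cc12"),
    Scaffold("coumarin", "O=C1C=Cc2cc{R1}c{R2}cc2O1"),
    Scaffold("chromone", "O=C1C=COc2cc{R1}c{R2}cc12"),
    Scaffold("benzodioxole", "C1Oc2cc{R1}c{R2}cc2O1"),
    # filler scaffolds: drug-like variety, not tied to any planted rule
    Scaffold("naphthalene", "c1ccc2cc{R1}c{R2}cc2c1"),
    Scaffold("biphenyl", "c1ccc(cc1)-c1cc{R1}c{R2}cc1"),
    Scaffold("benzophenone", "O=C(c1ccccc1)c1cc{R1}c{R2}cc1"),
    Scaffold("anisole", "COc1cc{R1}c{R2}cc1"),
    Scaffold("benzenesulfonamide", "NS(=O)(=O)c1cc{R1}c{R2}cc1"),
    Scaffold("acetanilide", "CC(=O)Nc1cc{R1}c{R2}cc1"),
    Scaffold("benzoic_acid", "OC(=O)c1cc{R1}c{R2}cc1"),
    Scaffold("aspirin", "CC(=O)Oc1cc{R1}c{R2}cc1C(=O)O"),
    Scaffold("phenylpiperazine", "C1CN(CCN1)c1cc{R1}c{R2}cc1"),
    Scaffold("picoline", "Cc1cc{R1}c{R2}cn1"),
    Scaffold("pyrimidine", "c1cc{R1}nc{R2}n1"),
    Scaffold("piperidine", "C1CC{R1}CC{R2}N1"),
    Scaffold("phenylmorpholine", "O1CCN(CC1)c1cc{R1}c{R2}cc1"),
    Scaffold("cyclohexanecarboxylic", "OC(=O)C1CC{R1}CC{R2}C1"),
    Scaffold("furamide", "NC(=O)c1cc{R1}c{R2}o1"),
    Scaffold("methylthiophene", "Cc1cc{R1}c{R2}s1"),
    Scaffold("pyrrole_ester", "COC(=O)c1cc{R1}c{R2}[nH]1"),
    Scaffold("phenylimidazole", "Cn1ccnc1-c1cc{R1}c{R2}cc1"),
    Scaffold("benzyl_alcohol", "OCc1cc{R1}c{R2}cc1"),
    Scaffold("cinnamic_acid", "OC(=O)C=Cc1cc{R1}c{R2}cc1"),
    Scaffold("phenethylamine", "NCCc1cc{R1}c{R2}cc1"),
    Scaffold("benzamide", "CNC(=O)c1cc{R1}c{R2}cc1"),
    Scaffold("diphenyl_ether", "c1ccc(cc1)Oc1cc{R1}c{R2}cc1"),
    Scaffold("indanone", "O=C1CCc2cc{R1}c{R2}cc12"),
    Scaffold("tetralin", "C1CCc2cc{R1}c{R2}cc2C1"),
    Scaffold("quinolinone", "O=C1C=Cc2cc{R1}c{R2}cc2N1"),
    Scaffold("warfarin_core", "CC(=O)CC(c1cc{R1}ccc1)c1c(O)c2cc{R2}ccc2oc1=O"),
    Scaffold("naproxen_core", "COc1cc{R1}c2cc(C(C)C(=O)O)cc{R2}c2c1"),
)

N_RULE_SCAFFOLDS = 14

#: Reference class-imbalance profile: interaction counts per CYP class in a
#: realistic curated corpus of 2345 drug pairs (CYP3A4 dominates at ~69%).
REFERENCE_CORPUS_PROFILE: dict[str, int] = {
    "CYP1A2": 132,
    "CYP2B6": 27,
    "CYP2C19": 80,
    "CYP2C8": 55,
    "CYP2C9": 204,
    "CYP2D6": 231,
    "CYP3A4": 1616,
}


@dataclass(frozen=True)
class PlantedRule:
    """Label a pair with ``activity`` when one molecule carries
    ``feature_a`` and the other carries ``feature_b`` (order-free)."""

    activity: str
    feature_a: str
    feature_b: str
    noise: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")


# ------------------------------------------------------------------ library

def generate_library(seed: int, n: int) -> list[tuple[str, str]]:
    """Deterministically generate ``n`` valid single-component molecules.

    The first two records are always warfarin and naproxen with their
    canonical SMILES; the remainder cycles round-robin through the curated
    scaffolds, decorating each with a seeded, non-repeating choice of
    substituent combinations.  The same seed yields an identical list.
    """
    if n < 10:
        raise ValueError("library size must be at least 10")
    rng = np.random.default_rng(seed)
    combos = [(r1, r2) for r1 in DECORATIONS for r2 in DECORATIONS]
    per_scaffold: list[list[tuple[str, str]]] = []
    for _ in SCAFFOLDS:
        order = rng.permutation(len(combos))
        per_scaffold.append([combos[i] for i in order])

    records: list[tuple[str, str]] = [
        ("warfarin", WARFARIN_SMILES),
        ("naproxen", NAPROXEN_SMILES),
    ]
    used = [0] * len(SCAFFOLDS)
    for j in range(n - 2):
        s = j % len(SCAFFOLDS)
        scaffold = SCAFFOLDS[s]
        if used[s] >= len(combos):
            raise PosmnaError(
                f"decoration space of scaffold {scaffold.name!r} exhausted; "
                f"maximum library size is {2 + len(SCAFFOLDS) * len(combos)}"
            )
        r1, r2 = per_scaffold[s][used[s]]
        used[s] += 1
        records.append((f"{scaffold.name}_{used[s]:03d}", scaffold.realize(r1, r2)))
    return records


def library_graphs(records: Sequence[tuple[str, str]]) -> dict[str, MolecularGraph]:
    """Parse library records into prepared graphs (validates every SMILES)."""
    return {rid: prepare(smi, record_id=rid) for rid, smi in records}


def _scaffold_of(molecule_id: str) -> str:
    return molecule_id.rsplit("_", 1)[0] if "_" in molecule_id else molecule_id


def _mna_sets(library) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for rid, mol in dict(library).items():
        if isinstance(mol, MolecularGraph):
            g = mol
        else:
            g = prepare(mol, record_id=rid)
        out[rid] = mna_set(g, DEFAULT_LEVEL).descriptors
    return out


# -------------------------------------------------------------------- rules

def default_rules(
    library, activities=CYP_ACTIVITIES, noise: float = 0.0
) -> list[PlantedRule]:
    """Derive one planted rule per activity from a generated library.

    Activity *i* is tied to scaffold families ``2i`` and ``2i+1`` of the
    curated list; its rule features are descriptor strings common to every
    member of the family and absent from every other library molecule, so
    the rule is exactly recoverable from structure.
    """
    sets = _mna_sets(library)
    families: dict[str, list[str]] = {}
    for rid in sets:
        families.setdefault(_scaffold_of(rid), []).append(rid)

    def family_feature(scaffold_name: str) -> str:
        members = families.get(scaffold_name, [])
        if not members:
            raise PosmnaError(
                f"library contains no molecules of scaffold {scaffold_name!r}"
            )
        common = frozenset.intersection(*(sets[m] for m in members))
        outside: set[str] = set()
        for rid, s in sets.items():
            if _scaffold_of(rid) != scaffold_name:
                outside |= s
        exclusive = common - outside
        if not exclusive:
            raise PosmnaError(
                f"no exclusive core descriptor for scaffold {scaffold_name!r}"
            )
        return min(exclusive, key=collation_key)

    rules = []
    for i, activity in enumerate(activities):
        sa = SCAFFOLDS[2 * i].name
        sb = SCAFFOLDS[2 * i + 1].name
        rules.append(
            PlantedRule(activity, family_feature(sa), family_feature(sb), noise)
        )
    return rules


# -------------------------------------------------------------- pair tables

def _allocate(n_pairs: int, activities, profile: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder proportional allocation with a floor of one pair."""
    weights = np.array([profile[a] for a in activities], dtype=float)
    exact = n_pairs * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for j in np.argsort(-remainder)[: n_pairs - counts.sum()]:
        counts[j] += 1
    # every modeled class needs at least one pair
    while (counts == 0).any():
        counts[int(np.argmin(counts))] += 1
        counts[int(np.argmax(counts))] -= 1
    return dict(zip(activities, (int(c) for c in counts)))


def generate_pair_table(
    seed: int,
    library,
    n_pairs: int,
    rules: Sequence[PlantedRule] | None = None,
    imbalance: Mapping[str, int] | str = "reference",
) -> tuple[list[tuple[str, str, str]], dict]:
    """Generate a labeled pair table plus its ground-truth manifest.

    Pairs for each activity are sampled (without replacement, unordered,
    distinct molecules) from the cross product of the molecules carrying the
    rule's two features; the planted label is then kept with probability
    ``1 - noise`` or replaced by a uniformly chosen different activity.
    Returns ``(rows, truth)`` where rows are ``(id_a, id_b, activity)``
    sorted by pair key and truth records planted labels and counts.
    """
    rng = np.random.default_rng(seed)
    sets = _mna_sets(library)
    if rules is None:
        rules = default_rules(library)
    activities = [r.activity for r in rules]
    if isinstance(imbalance, str):
        if imbalance not in ("table1", "reference"):
            raise PosmnaError(f"unknown imbalance profile {imbalance!r}")
        profile = REFERENCE_CORPUS_PROFILE
    else:
        profile = dict(imbalance)
    allocation = _allocate(n_pairs, activities, profile)

    rows: list[tuple[str, str, str]] = []
    planted: dict[str, str] = {}
    observed_counts = {a: 0 for a in activities}
    for rule in rules:
        cand_a = sorted(rid for rid, s in sets.items() if rule.feature_a in s)
        cand_b = sorted(rid for rid, s in sets.items() if rule.feature_b in s)
        if not cand_a or not cand_b:
            raise PosmnaError(
                f"rule for {rule.activity!r} is unsatisfiable: feature absent "
                "from the library"
            )
        combos = sorted(
            {pair_key(x, y) for x in cand_a for y in cand_b if x != y}
        )
        need = allocation[rule.activity]
        if need > len(combos):
            raise PosmnaError(
                f"activity {rule.activity!r} needs {need} distinct pairs but "
                f"the library supports only {len(combos)}; enlarge the library"
            )
        chosen = [combos[i] for i in rng.choice(len(combos), size=need, replace=False)]
        others = [a for a in activities if a != rule.activity]
        # flip destinations follow the class-imbalance profile so that every
        # class keeps a noise fraction of about epsilon; a uniform destination
        # would make the rarest classes majority-noise under heavy imbalance
        w = np.array([profile[a] for a in others], dtype=float)
        w /= w.sum()
        for key in chosen:
            label = rule.activity
            if rule.noise > 0 and rng.random() < rule.noise:
                label = others[rng.choice(len(others), p=w)]
            rows.append((key[0], key[1], label))
            planted["|".join(key)] = rule.activity
            observed_counts[label] += 1

    rows.sort()
    truth = {
        "planted": planted,
        "planted_counts": dict(allocation),
        "observed_counts": observed_counts,
        "rules": [
            {
                "activity": r.activity,
                "feature_a": r.feature_a,
                "feature_b": r.feature_b,
                "noise": r.noise,
            }
            for r in rules
        ],
    }
    return rows, truth


def permute_pair_labels(
    rows: Sequence[tuple[str, str, str]], seed: int
) -> list[tuple[str, str, str]]:
    """Shuffle the activity column across pairs (null model for validation)."""
    rng = np.random.default_rng(seed)
    labels = [r[2] for r in rows]
    perm = rng.permutation(len(labels))
    return [(r[0], r[1], labels[perm[i]]) for i, r in enumerate(rows)]
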