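"""Independent naive reference implementation of the MNA descriptor grammar.

Written deliberately without reusing any package code: plain recursion over
adjacency dicts, ring atoms from networkx cycle-basis membership, and a
hand-rolled comparison function.  Serves as the oracle the production
descriptor generator is checked against.
"""

import functools

import networkx as nx

# '(' < ')' < letters (ASCII) < '-' ; space lowest
_ORDER = {" ": 0, "(": 1, ")": 2, "-": 999}


def _char_rank(c):
    return _ORDER.get(c, 3 + ord(c))


def ref_compare(s1, s2):
    for c1, c2 in zip(s1, s2):
        r1, r2 = _char_rank(c1), _char_rank(c2)
        if r1 != r2:
            return -1 if r1 < r2 else 1
    if len(s1) == len(s2):
        return 0
    return -1 if len(s1) < len(s2) else 1


def ref_sorted(strings):
    return sorted(strings, key=functools.cmp_to_key(ref_compare))


def ref_ring_atoms(elements, edges):
    """Atoms lying on at least one cycle, via networkx cycle basis."""
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    g.add_edges_from(edges)
    ring = set()
    for comp in nx.connected_components(g):
        for cycle in nx.cycle_basis(g.subgraph(comp)):
            ring.update(cycle)
    return ring


def ref_descriptor(elements, edges, center, level):
    """Naive recursive MNA descriptor of ``center`` at ``level``."""
    ring = ref_ring_atoms(elements, edges)
    neighbors = {i: set() for i in range(len(elements))}
    for i, j in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)

    def label(i):
        mark = "" if (i in ring and elements[i] != "H") else "-"
        return mark + elements[i]

    def descr(i, k):
        if k == 0:
            return label(i)
        inner = ref_sorted([descr(j, k - 1) for j in neighbors[i]])
        return label(i) + "(" + "".join(inner) + ")"

    return descr(center, level)


def ref_mna_set(elements, edges, level=2):
    """Unique level-``level`` descriptors over non-hydrogen centers."""
    return {
        ref_descriptor(elements, edges, i, level)
        for i, el in enumerate(elements)
        if el != "H"
    }


def ref_posmna(set_a, set_b):
    """Direct product with canonically ordered components."""
    out = set()
    for x in set_a:
        for y in set_b:
            if ref_compare(x, y) <= 0:
                out.add(x + " " + y)
            else:
                out.add(y + " " + x)
    return out
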