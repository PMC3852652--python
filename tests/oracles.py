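"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the optimisations used by the package: the local
alignment oracle enumerates gap lengths explicitly instead of the affine
three-state recursion; the MCS oracle enumerates connected atom subsets and
tests induced subgraph isomorphism with networkx; the superposition oracle
goes through scipy's independent rotation-fitting routine.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation


def sw_score_bruteforce(a: str, b: str, matrix, gap_open: float,
                        gap_extend: float) -> float:
    """Optimal local-alignment score; gap of length k costs open + k*extend.

    O(n^2 m^2) dynamic programme over alignments ending in a matched column:
    M[i][j] is the best score of a local alignment whose last column pairs
    a[i] with b[j]; predecessors are chained across explicit gap lengths.
    """
    n, m = len(a), len(b)

    def gap(k: int) -> float:
        return 0.0 if k == 0 else gap_open + k * gap_extend

    best = 0.0
    M = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(matrix[a[i - 1], b[j - 1]])
            prev = 0.0
            for i2 in range(1, i):
                for j2 in range(1, j):
                    cand = M[i2][j2] - gap(i - i2 - 1) - gap(j - j2 - 1)
                    if cand > prev:
                        prev = cand
            M[i][j] = s + prev
            best = max(best, M[i][j])
    return best


def _connected_subsets(g: nx.Graph, size: int):
    for nodes in itertools.combinations(sorted(g.nodes), size):
        sub = g.subgraph(nodes)
        if nx.is_connected(sub):
            yield nodes


def mcs_size_bruteforce(a, b) -> int:
    """Largest connected induced common subgraph by exhaustive enumeration."""
    ga, gb = a.to_networkx(), b.to_networkx()
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    node_match = nx.isomorphism.categorical_node_match("element", None)
    edge_match = nx.isomorphism.categorical_edge_match("order", None)
    for size in range(ga.number_of_nodes(), 0, -1):
        for nodes in _connected_subsets(ga, size):
            pattern = ga.subgraph(nodes)
            gm = nx.isomorphism.GraphMatcher(gb, pattern, node_match=node_match,
                                             edge_match=edge_match)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


def superpose_oracle(fixed: np.ndarray, mobile: np.ndarray):
    """Optimal rotation/translation/RMSD via scipy's rotation fitting."""
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(fixed - cf, mobile - cm)
    rotation = rot.as_matrix()
    translation = cf - rotation @ cm
    diff = mobile @ rotation.T + translation - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / len(fixed)))
    return rotation, translation, rmsd


def random_molecule_graph(rng: np.random.Generator, max_atoms: int = 8):
    """A random small connected element-labelled bond-typed graph."""
    from ligsearch.chem import MoleculeGraph

    n = int(rng.integers(1, max_atoms + 1))
    elements = [str(rng.choice(["C", "N", "O"])) for _ in range(n)]
    bonds = []
    for i in range(1, n):                      # random spanning tree
        j = int(rng.integers(0, i))
        bonds.append((j, i, float(rng.choice([1.0, 2.0]))))
    extra = int(rng.integers(0, max(1, n // 2)))
    for _ in range(extra):
        i, j = sorted(rng.choice(n, size=2, replace=False)) if n > 1 else (0, 0)
        if i != j and not any(x == (min(i, j), max(i, j)) for x, _ in
                              [((bi, bj), o) for bi, bj, o in bonds]):
            bonds.append((int(i), int(j), 1.0))
    return MoleculeGraph(name=f"rnd{rng.integers(1e6)}", elements=tuple(elements),
                         bonds=tuple(bonds))


def mass_oracle(elements, n_hydrogens: int) -> float:
    """Independent mass sum from a frozen standard-atomic-weight table."""
    masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
              "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904}
    return sum(masses[e] for e in elements) + n_hydrogens * masses["H"]
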