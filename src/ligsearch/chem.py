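"""Small-molecule graphs, maximum-common-subgraph similarity and clustering.

Molecules are handled as element-labelled, bond-typed graphs over heavy
atoms.  Pairwise similarity is the atom-count Tanimoto over the maximum
connected common subgraph (MCS), and candidate ligands are grouped by
complete-linkage agglomerative clustering so that every pair inside a
cluster — including the two most distant members — stays at or above the
similarity cutoff (default 0.4).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

logger = logging.getLogger(__name__)

#: bond order used for aromatic bonds
AROMATIC_ORDER = 1.5

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_ORDER,
}

_H_MASS = 1.008


class ChemError(ValueError):
    """Raised for invalid molecule graphs or unknown elements."""


@dataclass
class MoleculeGraph:
    """Element-labelled, bond-typed graph of the heavy atoms of a molecule.

    Parameters
    ----------
    name:
        Identifier of the molecule (het code, compound id, ...).
    elements:
        Element symbol per heavy atom; index in this sequence is the node id.
    bonds:
        ``(i, j, order)`` triples with ``order`` in ``{1, 2, 3, 1.5}``
        (1.5 marks aromatic bonds).
    """

    name: str
    elements: tuple
    bonds: tuple
    _rdkit: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.elements = tuple(str(e).strip() for e in self.elements)
        norm = []
        for i, j, order in self.bonds:
            if i == j:
                raise ChemError(f"self-loop on atom {i} in {self.name!r}")
            if not (0 <= i < len(self.elements) and 0 <= j < len(self.elements)):
                raise ChemError(f"bond ({i},{j}) out of range in {self.name!r}")
            norm.append((min(i, j), max(i, j), float(order)))
        self.bonds = tuple(sorted(set(norm)))
        adj = {i: {} for i in range(len(self.elements))}
        for i, j, order in self.bonds:
            adj[i][j] = order
            adj[j][i] = order
        self._adj = adj

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> Mapping[int, float]:
        return self._adj[i]

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "MoleculeGraph":
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             _RDKIT_BOND_ORDER.get(b.GetBondType(), 1.0))
            for b in mol.GetBonds()
        )
        if not name and mol.HasProp("_Name"):
            name = mol.GetProp("_Name")
        return cls(name=name, elements=elements, bonds=bonds, _rdkit=mol)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MoleculeGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemError(f"unparsable SMILES {smiles!r}")
        return cls.from_rdkit(mol, name=name or smiles)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


def is_isomorphic(a: MoleculeGraph, b: MoleculeGraph) -> bool:
    """Exact-molecule identity: element- and bond-order-preserving isomorphism."""
    if a.n_atoms != b.n_atoms or len(a.bonds) != len(b.bonds):
        return False
    if sorted(a.elements) != sorted(b.elements):
        return False
    return nx.is_isomorphic(
        a.to_networkx(), b.to_networkx(),
        node_match=nx.isomorphism.categorical_node_match("element", None),
        edge_match=nx.isomorphism.categorical_edge_match("order", None),
    )


# ---------------------------------------------------------------------------
# Maximum common subgraph
# ---------------------------------------------------------------------------

@dataclass
class McsResult:
    """A maximum connected common subgraph between two molecules."""

    mapping: dict          # atom index in ``a`` -> atom index in ``b``
    size: int
    exact: bool = True     # False when the time budget truncated the search

    def __post_init__(self):
        self.size = len(self.mapping)


@dataclass
class SimilarityScore:
    """Tanimoto similarity over the MCS heavy-atom count."""

    value: float
    mcs_size: int
    exact: bool = True


def mcs(a: MoleculeGraph, b: MoleculeGraph, size_limit: int = 60,
        time_budget_s: float = 10.0) -> McsResult:
    """Maximum connected common subgraph under element and bond-order matching.

    The match is induced: two mapped atoms are bonded in one molecule if and
    only if they are bonded, with the same order, in the other.  Pairs whose
    larger molecule exceeds ``size_limit`` heavy atoms, or searches that
    exhaust ``time_budget_s``, fall back to the best mapping found so far and
    are flagged ``exact=False``.
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        return McsResult(mapping={}, size=0)
    budget_ok = max(a.n_atoms, b.n_atoms) <= size_limit
    if not budget_ok:
        logger.warning("MCS %s/%s exceeds %d-atom exact-search limit; "
                       "result may be a lower bound", a.name, b.name, size_limit)
    deadline = time.monotonic() + time_budget_s

    adj_a, adj_b = a._adj, b._adj
    best: dict = {}
    timed_out = False

    # global upper bound from the element multiset intersection
    from collections import Counter
    count_a, count_b = Counter(a.elements), Counter(b.elements)
    elem_bound = sum(min(count_a[e], count_b[e]) for e in count_a)

    def candidate_pairs(mapping, used_b, excluded):
        out = []
        for u in range(a.n_atoms):
            if u in mapping:
                continue
            for v in range(b.n_atoms):
                if v in used_b or a.elements[u] != b.elements[v]:
                    continue
                if (u, v) in excluded:
                    continue
                connected = not mapping
                ok = True
                for u0, v0 in mapping.items():
                    oa = adj_a[u].get(u0)
                    ob = adj_b[v].get(v0)
                    if (oa is None) != (ob is None) or (oa is not None and oa != ob):
                        ok = False
                        break
                    if oa is not None:
                        connected = True
                if ok and connected:
                    out.append((u, v))
        return out

    def extend(mapping, used_b, excluded):
        nonlocal best, timed_out
        if timed_out or time.monotonic() > deadline:
            timed_out = True
            return
        if len(mapping) > len(best):
            best = dict(mapping)
        if min(a.n_atoms, b.n_atoms, elem_bound) <= len(best):
            return
        cands = candidate_pairs(mapping, used_b, excluded)
        local_excluded = set(excluded)
        for u, v in cands:
            mapping[u] = v
            used_b.add(v)
            extend(mapping, used_b, local_excluded)
            del mapping[u]
            used_b.discard(v)
            local_excluded.add((u, v))
            if timed_out:
                return
            if len(best) == min(a.n_atoms, b.n_atoms, elem_bound):
                return

    extend({}, set(), set())
    return McsResult(mapping=best, size=len(best), exact=not timed_out and budget_ok)


def similarity(a: MoleculeGraph, b: MoleculeGraph, **mcs_kwargs) -> SimilarityScore:
    """Atom-count Tanimoto similarity |MCS| / (|a| + |b| - |MCS|)."""
    if a.n_atoms == 0 or b.n_atoms == 0:
        return SimilarityScore(value=0.0, mcs_size=0)
    res = mcs(a, b, **mcs_kwargs)
    denom = a.n_atoms + b.n_atoms - res.size
    return SimilarityScore(value=res.size / denom if denom else 0.0,
                           mcs_size=res.size, exact=res.exact)


# ---------------------------------------------------------------------------
# Complete-linkage clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A group of candidate ligands whose pairwise similarity meets the cutoff."""

    cluster_id: str
    members: list
    rank: Optional[int] = None
    best_pdb_score: Optional[float] = None


def cluster_from_matrix(ids: Sequence[str], sim, cutoff: float = 0.4) -> list:
    """Complete-linkage agglomeration on a precomputed similarity matrix.

    Clusters merge while the *minimum* cross-pair similarity of the merged
    group stays >= ``cutoff``; ties on linkage value are broken by the
    lexicographically smallest combined member-id tuple.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    ids = list(ids)
    n = len(ids)
    if n == 0:
        return []
    index = {mid: k for k, mid in enumerate(ids)}
    groups = [[mid] for mid in sorted(ids)]

    def linkage(g1, g2):
        return min(sim[index[x]][index[y]] for x in g1 for y in g2)

    while len(groups) > 1:
        best_key, best_pair = None, None
        for p, q in itertools.combinations(range(len(groups)), 2):
            v = linkage(groups[p], groups[q])
            if v < cutoff:
                continue
            key = (-v, tuple(sorted(groups[p] + groups[q])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (p, q)
        if best_pair is None:
            break
        p, q = best_pair
        merged = sorted(groups[p] + groups[q])
        groups = [g for k, g in enumerate(groups) if k not in (p, q)] + [merged]
        groups.sort(key=lambda g: g[0])

    return [Cluster(cluster_id=g[0], members=list(g)) for g in sorted(groups, key=lambda g: g[0])]


def similarity_matrix(mols: Sequence[MoleculeGraph], **mcs_kwargs):
    """All-by-all Tanimoto similarity matrix (nested lists, symmetric)."""
    n = len(mols)
    sim = [[1.0] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        v = similarity(mols[i], mols[j], **mcs_kwargs).value
        sim[i][j] = sim[j][i] = v
    return sim


def cluster_molecules(mols: Sequence[MoleculeGraph], cutoff: float = 0.4,
                      **mcs_kwargs) -> list:
    """Cluster molecules by MCS Tanimoto similarity at ``cutoff``."""
    if not mols:
        return []
    names = [m.name for m in mols]
    if len(set(names)) != len(names):
        raise ChemError("molecule names must be unique for clustering")
    sim = similarity_matrix(mols, **mcs_kwargs)
    return cluster_from_matrix(names, sim, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Molecular properties
# ---------------------------------------------------------------------------

@dataclass
class MolecularProperties:
    mol_weight: float           # Da, hydrogens implicit by valence
    heavy_atoms: int
    total_atoms: int            # heavy atoms + implicit hydrogens
    logp: Optional[float] = None
    polar_surface_area: Optional[float] = None


def properties(mol: MoleculeGraph) -> MolecularProperties:
    """Molecular weight, atom counts and (when derivable) logP / TPSA.

    Molecules built from SMILES or SDF carry an RDKit molecule and get the
    RDKit descriptors; bare graphs fall back to a mass sum with implicit
    hydrogens from default element valences, and logP/PSA stay absent.
    """
    if mol._rdkit is not None:
        m = mol._rdkit
        return MolecularProperties(
            mol_weight=float(Descriptors.MolWt(m)),
            heavy_atoms=int(m.GetNumHeavyAtoms()),
            total_atoms=int(Chem.AddHs(m).GetNumAtoms()),
            logp=float(Crippen.MolLogP(m)),
            polar_surface_area=float(rdMolDescriptors.CalcTPSA(m)),
        )
    pt = Chem.GetPeriodicTable()
    weight = 0.0
    n_h = 0
    for i, el in enumerate(mol.elements):
        try:
            z = pt.GetAtomicNumber(el)
        except Exception as exc:
            raise ChemError(f"unknown element {el!r} in {mol.name!r}") from exc
        if z == 0:
            raise ChemError(f"unknown element {el!r} in {mol.name!r}")
        weight += pt.GetAtomicWeight(z)
        valence = pt.GetDefaultValence(z)
        if valence > 0:
            order_sum = int(round(sum(mol.neighbors(i).values())))
            n_h += max(0, valence - order_sum)
    return MolecularProperties(
        mol_weight=weight + n_h * _H_MASS,
        heavy_atoms=mol.n_atoms,
        total_atoms=mol.n_atoms + n_h,
    )
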