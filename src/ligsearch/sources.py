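"""Compound-source records and the per-database filters applied before ranking.

Records emulate exports from protein-to-compound resources (ChEMBL-, ChEBI-
and KEGG-style tables).  ChEMBL records must carry a binding constant and an
IC50 of at most 100 nM when one is given; ChEBI records must have at least
four atoms (implicit hydrogens included) and a molecular weight of at least
50 Da; KEGG records pass unfiltered.  The filtered sources are then unioned
with duplicates removed by exact molecular-graph identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import chem

logger = logging.getLogger(__name__)

SOURCES = ("chembl", "chebi", "kegg")


@dataclass
class CompoundRecord:
    """One compound associated with a protein in a source database."""

    compound_id: str
    source: str
    molecule: chem.MoleculeGraph
    ic50_nM: Optional[float] = None
    has_binding_constant: bool = False
    xref_count: Optional[int] = None
    assoc_protein_id: Optional[str] = None
    assoc_identity_pct: Optional[float] = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.ic50_nM is not None:
            self.ic50_nM = float(self.ic50_nM)
            if self.ic50_nM <= 0:
                raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM}")
            self.has_binding_constant = True
        if self.xref_count is not None and self.xref_count < 0:
            raise ValueError("xref_count must be non-negative")


def filter_chembl(records: Iterable[CompoundRecord],
                  max_ic50_nM: float = 100.0) -> list:
    """Keep records with a binding constant and IC50 <= ``max_ic50_nM``.

    An IC50 of exactly the threshold survives (only values strictly above it
    are excluded); records whose binding constant is of another kind (no IC50
    value) survive as well.
    """
    out = []
    for r in records:
        if r.source != "chembl":
            raise ValueError(f"filter_chembl given {r.source!r} record {r.compound_id!r}")
        if not r.has_binding_constant:
            continue
        if r.ic50_nM is not None and r.ic50_nM > max_ic50_nM:
            continue
        out.append(r)
    return out


def filter_chebi(records: Iterable[CompoundRecord], min_atoms: int = 4,
                 min_weight: float = 50.0, count_implicit_h: bool = True) -> list:
    """Drop very small molecules: < ``min_atoms`` atoms or < ``min_weight`` Da.

    By default the atom count includes implicit hydrogens, so e.g. hydrogen
    peroxide (2 heavy atoms, 4 total) passes the atom rule.
    """
    out = []
    for r in records:
        if r.source != "chebi":
            raise ValueError(f"filter_chebi given {r.source!r} record {r.compound_id!r}")
        props = chem.properties(r.molecule)
        n_atoms = props.total_atoms if count_implicit_h else props.heavy_atoms
        if n_atoms < min_atoms or props.mol_weight < min_weight:
            continue
        out.append(r)
    return out


def _metadata_rank(r: CompoundRecord) -> tuple:
    return (1 if r.has_binding_constant else 0,
            1 if r.xref_count is not None else 0)


def _bucket_key(mol: chem.MoleculeGraph) -> tuple:
    return (tuple(sorted(mol.elements)),
            tuple(sorted(order for _, _, order in mol.bonds)))


def dedup_union(*collections: Iterable[CompoundRecord]) -> list:
    """Union the collections, removing exact-molecule duplicates.

    Identity is element- and bond-order-preserving graph isomorphism.  On a
    collision the record with the most metadata survives (binding constant
    beats cross-reference count beats first-seen); the survivor keeps the
    first-seen record's position so output order is reproducible.
    """
    kept: list = []
    buckets: dict = {}
    for coll in collections:
        for r in coll:
            key = _bucket_key(r.molecule)
            hit = None
            for pos in buckets.get(key, ()):
                if chem.is_isomorphic(kept[pos].molecule, r.molecule):
                    hit = pos
                    break
            if hit is None:
                buckets.setdefault(key, []).append(len(kept))
                kept.append(r)
            elif _metadata_rank(r) > _metadata_rank(kept[hit]):
                kept[hit] = r
    return kept
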