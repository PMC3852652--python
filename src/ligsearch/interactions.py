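"""Ligand–protein interaction detection and conservation-weighted scoring.

Each ligand instance is scored against the query through the alignment of
its parent protein: every hydrogen bond contributes 3 points when the
contacted residue is identical to the corresponding query residue, 2 when
similar (positive substitution-matrix score), 1 otherwise and -1 when the
residue aligns to a gap; nonbonded contacts contribute 2/1/0/-1 on the same
scale, with at most one contact counted per protein residue.  The score is
reported as achieved/maximum, where the maximum re-scores the same
interactions as if every contacted residue were identical — so a hit
identical to the query always achieves its ceiling.

Hydrogen bonds are distance-only between polar heavy atoms (N, O, S within
3.35 Å); deposited coordinates usually lack hydrogens, so no angle term is
applied.  Nonbonded contacts are heavy-atom pairs within 3.9 Å.  Both
thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .align import load_matrix
from .formats_io import Atom, LigandInstance, Residue, Structure

logger = logging.getLogger(__name__)

POLAR_ELEMENTS = {"N", "O", "S"}
CONSERVATION_CLASSES = ("identical", "similar", "other", "gap")


@dataclass
class ScoringScheme:
    """Interaction weights by conservation class, plus geometric thresholds."""

    hb_identical: int = 3
    hb_similar: int = 2
    hb_other: int = 1
    hb_gap: int = -1
    nb_identical: int = 2
    nb_similar: int = 1
    nb_other: int = 0
    nb_gap: int = -1
    hbond_max_dist: float = 3.35
    contact_max_dist: float = 3.9

    def __post_init__(self):
        if not (self.hb_identical > self.hb_similar > self.hb_other > self.hb_gap):
            raise ValueError("hydrogen-bond weights must be strictly decreasing")
        if not (self.nb_identical > self.nb_similar > self.nb_other > self.nb_gap):
            raise ValueError("contact weights must be strictly decreasing")

    def weight(self, kind: str, conservation: str) -> int:
        prefix = "hb" if kind == "hbond" else "nb"
        return getattr(self, f"{prefix}_{conservation}")

    def ceiling(self, kind: str) -> int:
        return self.hb_identical if kind == "hbond" else self.nb_identical


@dataclass
class InteractionRecord:
    ligand_atom: Atom
    protein_residue: Residue
    kind: str                       # 'hbond' | 'contact'
    distance: float
    conservation: Optional[str] = None

    @property
    def residue_key(self) -> tuple:
        return self.protein_residue.key


@dataclass
class LigandScore:
    """Conservation-weighted interaction score of one ligand instance."""

    ligand: LigandInstance
    achieved: int
    maximum: int
    per_residue: List[InteractionRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.achieved > self.maximum:
            raise ValueError("achieved score cannot exceed the maximum")

    @property
    def as_fraction(self) -> str:
        return f"{self.achieved}/{self.maximum}"


def _polymer_atoms(protein: Structure, polar_only: bool):
    atoms, residues = [], []
    for residues_list in protein.chains.values():
        for res in residues_list:
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                if polar_only and atom.element not in POLAR_ELEMENTS:
                    continue
                atoms.append(atom)
                residues.append(res)
    return atoms, residues


def _sorted_records(records: List[InteractionRecord]) -> List[InteractionRecord]:
    return sorted(records, key=lambda r: (r.residue_key, r.ligand_atom.name,
                                          r.distance))


def detect_hbonds(protein: Structure, ligand: LigandInstance,
                  scheme: ScoringScheme) -> List[InteractionRecord]:
    """Polar ligand atoms within ``hbond_max_dist`` of polar protein atoms.

    Each qualifying (ligand atom, protein atom) pair yields one record —
    every hydrogen bond counts individually.
    """
    prot_atoms, prot_residues = _polymer_atoms(protein, polar_only=True)
    lig_polar = [a for a in ligand.atoms if a.element in POLAR_ELEMENTS]
    if not prot_atoms or not lig_polar:
        return []
    tree = cKDTree(np.array([a.coords for a in prot_atoms]))
    records = []
    for lig_atom in lig_polar:
        for idx in tree.query_ball_point(lig_atom.coords, scheme.hbond_max_dist):
            dist = float(np.linalg.norm(lig_atom.coords - prot_atoms[idx].coords))
            records.append(InteractionRecord(
                ligand_atom=lig_atom, protein_residue=prot_residues[idx],
                kind="hbond", distance=dist))
    return _sorted_records(records)


def detect_contacts(protein: Structure, ligand: LigandInstance,
                    scheme: ScoringScheme,
                    hbonds: Optional[List[InteractionRecord]] = None
                    ) -> List[InteractionRecord]:
    """Nonbonded contacts, at most one per protein residue (closest pair).

    Residues that already make a hydrogen bond to the ligand accrue no
    contact record, so no residue is double-counted.  ``hbonds`` may be
    passed to avoid recomputing them.
    """
    if hbonds is None:
        hbonds = detect_hbonds(protein, ligand, scheme)
    hbond_residues = {r.residue_key for r in hbonds}
    prot_atoms, prot_residues = _polymer_atoms(protein, polar_only=False)
    lig_heavy = [a for a in ligand.atoms if a.element != "H"]
    if not prot_atoms or not lig_heavy:
        return []
    tree = cKDTree(np.array([a.coords for a in prot_atoms]))
    best: Dict[tuple, InteractionRecord] = {}
    for lig_atom in lig_heavy:
        for idx in tree.query_ball_point(lig_atom.coords, scheme.contact_max_dist):
            res = prot_residues[idx]
            if res.key in hbond_residues:
                continue
            dist = float(np.linalg.norm(lig_atom.coords - prot_atoms[idx].coords))
            cur = best.get(res.key)
            if cur is None or dist < cur.distance:
                best[res.key] = InteractionRecord(
                    ligand_atom=lig_atom, protein_residue=res,
                    kind="contact", distance=dist)
    return _sorted_records(list(best.values()))


def classify_conservation(record: InteractionRecord, hit_pos: Optional[int],
                          query_to_hit: Mapping[int, int], query_seq: str,
                          hit_seq: str, matrix=None) -> str:
    """Conservation class of the contacted residue relative to the query.

    ``hit_pos`` is the 1-based position of the contacted residue in the hit
    sequence (``None`` when it falls outside the searched entry).  A residue
    aligned to no query position is a ``gap``; otherwise it is ``identical``
    when the query residue type matches, ``similar`` when the substitution
    matrix scores the pair positively, and ``other`` otherwise.  The record's
    ``conservation`` field is set as a side effect.
    """
    if isinstance(matrix, str) or matrix is None:
        matrix = load_matrix(matrix or "BLOSUM62")
    hit_to_query = {h: q for q, h in query_to_hit.items()}
    if hit_pos is None or hit_pos not in hit_to_query:
        record.conservation = "gap"
        return "gap"
    qpos = hit_to_query[hit_pos]
    q_aa = query_seq[qpos - 1]
    h_aa = hit_seq[hit_pos - 1]
    if q_aa == h_aa:
        cls = "identical"
    else:
        try:
            score = matrix[q_aa, h_aa]
        except (KeyError, IndexError):
            score = -1
        cls = "similar" if score > 0 else "other"
    record.conservation = cls
    return cls


def score_ligand(ligand: LigandInstance, hbonds: Sequence[InteractionRecord],
                 contacts: Sequence[InteractionRecord],
                 scheme: ScoringScheme) -> LigandScore:
    """Sum the conservation-weighted interaction scores into achieved/maximum.

    Records must already be conservation-classified and (for contacts)
    per-residue deduplicated.
    """
    records = list(hbonds) + list(contacts)
    for r in records:
        if r.conservation not in CONSERVATION_CLASSES:
            raise ValueError(f"record {r.residue_key} not conservation-classified")
    achieved = sum(scheme.weight(r.kind, r.conservation) for r in records)
    maximum = sum(scheme.ceiling(r.kind) for r in records)
    return LigandScore(ligand=ligand, achieved=achieved, maximum=maximum,
                       per_residue=records)


_CLASS_ORDER = {c: i for i, c in enumerate(CONSERVATION_CLASSES)}


def merge_domain_scores(per_domain: Sequence[LigandScore],
                        scheme: ScoringScheme) -> LigandScore:
    """Merge the per-domain scores of one ligand instance.

    Ligands spanning several domains appear in more than one domain search;
    the union of their interaction records is re-scored with each protein
    residue counted once.  On collision, hydrogen-bond records beat contact
    records; duplicate hydrogen bonds (same ligand atom and residue) are
    kept once, preferring the better-conserved then closer record.
    """
    if not per_domain:
        raise ValueError("no scores to merge")
    keys = {s.ligand.key for s in per_domain}
    if len(keys) != 1:
        raise ValueError(f"cannot merge scores of different ligands: {sorted(keys)}")
    if len(per_domain) == 1:
        return per_domain[0]

    by_residue: Dict[tuple, List[InteractionRecord]] = {}
    for s in per_domain:
        for r in s.per_residue:
            by_residue.setdefault(r.residue_key, []).append(r)

    hbonds: List[InteractionRecord] = []
    contacts: List[InteractionRecord] = []
    for key in sorted(by_residue):
        records = by_residue[key]
        hb = [r for r in records if r.kind == "hbond"]
        if hb:
            seen: Dict[tuple, InteractionRecord] = {}
            for r in sorted(hb, key=lambda r: (_CLASS_ORDER[r.conservation],
                                               r.distance)):
                seen.setdefault((r.ligand_atom.name, round(r.distance, 3)), r)
            hbonds.extend(seen.values())
        else:
            contacts.append(min(records,
                                key=lambda r: (_CLASS_ORDER[r.conservation],
                                               r.distance)))
    return score_ligand(per_domain[0].ligand, _sorted_records(hbonds),
                        _sorted_records(contacts), scheme)
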