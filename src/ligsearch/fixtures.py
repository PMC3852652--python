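"""Synthetic inputs with known ground truth for every pipeline stage.

The generator builds idealised protein–ligand complexes on an extended-chain
backbone (3.8 Å CA spacing, fixed main-chain offsets): realism of the fold is
irrelevant to the scored method, only distances and labels matter.  Ligand
atoms are placed to realise each planted hydrogen bond or nonbonded contact
at its stated distance, in directions chosen so no unintended protein atom
falls within the detection thresholds — which is verified by running the
detectors before the fixture is returned.  Homolog sequences are mutated to
a target percent identity with binding-site conservation classes planted by
substitution-matrix sign, and ligand series are derived by successive
single-atom deletions so the Tanimoto similarity to the base molecule
decreases by a known amount at each step.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .align import load_matrix
from .chem import MoleculeGraph
from .domain_partition import DomainAnnotation
from .formats_io import Atom, LigandInstance, Residue, Structure, write_pdb
from .interactions import ScoringScheme, detect_contacts, detect_hbonds
from .sources import CompoundRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

CA_SPACING = 3.8
_N_OFFSET = np.array([-1.2, 0.8, 0.0])
_C_OFFSET = np.array([1.0, -0.9, 0.0])
_O_OFFSET = np.array([1.2, -2.1, 0.0])

DEFAULT_HBOND_DIST = 3.0
DEFAULT_CONTACT_DIST = 3.75


class FixtureError(ValueError):
    pass


@dataclass
class PlantedInteraction:
    residue_index: int          # 1-based position along the chain
    kind: str                   # 'hbond' | 'contact'
    distance: float = 0.0

    def __post_init__(self):
        if self.kind not in ("hbond", "contact"):
            raise FixtureError(f"unknown interaction kind {self.kind!r}")
        if self.distance == 0.0:
            self.distance = (DEFAULT_HBOND_DIST if self.kind == "hbond"
                             else DEFAULT_CONTACT_DIST)


@dataclass
class ComplexSpec:
    """Recipe for one synthetic complex."""

    seed: int = 0
    n_residues: int = 30
    sequence: Optional[str] = None
    interactions: List[PlantedInteraction] = field(default_factory=list)
    structure_id: str = "SYN1"
    chain_id: str = "A"
    het_code: str = "LIG"
    ligand_seq_num: int = 900
    rigid_motion: Optional[Tuple[np.ndarray, np.ndarray]] = None


def rigid_motion_from_seed(seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """A reproducible random proper rotation plus translation."""
    rng = np.random.default_rng(seed)
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-20.0, 20.0, size=3)
    return rotation, translation


def _backbone(index: int) -> Dict[str, np.ndarray]:
    ca = np.array([(index - 1) * CA_SPACING, 0.0, 0.0])
    return {"N": ca + _N_OFFSET, "CA": ca, "C": ca + _C_OFFSET,
            "O": ca + _O_OFFSET}


def make_complex(spec: ComplexSpec) -> Tuple[str, dict]:
    """Build a complex with the planted interactions; returns (PDB text, truth).

    Hydrogen bonds are realised by a ligand oxygen placed below the target
    residue's backbone O; contacts by a ligand carbon placed above the CA.
    The detectors are run on the built structure and must recover exactly
    the planted interaction set, otherwise the geometry request is rejected.
    """
    if spec.n_residues < 10:
        raise FixtureError("n_residues must be >= 10")
    rng = np.random.default_rng(spec.seed)
    sequence = spec.sequence or "".join(rng.choice(list(AMINO_ACIDS),
                                                   size=spec.n_residues))
    if len(sequence) != spec.n_residues:
        raise FixtureError("sequence length does not match n_residues")
    used = [p.residue_index for p in spec.interactions]
    if len(set(used)) != len(used):
        raise FixtureError("planted interactions must target distinct residues")
    if any(not 1 <= i <= spec.n_residues for i in used):
        raise FixtureError("planted residue index outside the chain")

    serial = 0
    residues = []
    for i, letter in enumerate(sequence, start=1):
        coords = _backbone(i)
        atoms = []
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(name=name, element=name[0], coords=coords[name],
                              serial=serial))
        residues.append(Residue(chain_id=spec.chain_id, seq_num=i,
                                insertion_code="", res_type=_THREE[letter],
                                atoms=atoms))

    lig_atoms = []
    truth_hb, truth_ct = [], []
    for k, planted in enumerate(sorted(spec.interactions,
                                       key=lambda p: p.residue_index), start=1):
        bb = _backbone(planted.residue_index)
        if planted.kind == "hbond":
            if not 2.5 <= planted.distance <= 3.35:
                raise FixtureError(
                    f"hbond distance {planted.distance} outside feasible 2.5-3.35")
            pos = bb["O"] + np.array([0.0, -planted.distance, 0.0])
            name, element = f"O{k}", "O"
            truth_hb.append((planted.residue_index, name, planted.distance))
        else:
            if not 3.4 <= planted.distance <= 3.9:
                raise FixtureError(
                    f"contact distance {planted.distance} outside feasible 3.4-3.9")
            pos = bb["CA"] + np.array([0.0, 0.0, planted.distance])
            name, element = f"C{k}", "C"
            truth_ct.append((planted.residue_index, name, planted.distance))
        serial += 1
        lig_atoms.append(Atom(name=name, element=element, coords=pos,
                              serial=serial))

    ligands = []
    conect: Dict[int, List[int]] = {}
    if lig_atoms:
        for a, b in zip(lig_atoms, lig_atoms[1:]):
            conect.setdefault(a.serial, []).append(b.serial)
            conect.setdefault(b.serial, []).append(a.serial)
        ligands.append(LigandInstance(
            structure_id=spec.structure_id, het_code=spec.het_code,
            chain_id=spec.chain_id, seq_num=spec.ligand_seq_num,
            atoms=lig_atoms))

    structure = Structure(id=spec.structure_id,
                          chains={spec.chain_id: residues},
                          seqres={spec.chain_id: sequence},
                          ligands=ligands, conect=conect)

    # the planted geometry must be exactly what the detectors see
    if ligands:
        scheme = ScoringScheme()
        hb = detect_hbonds(structure, ligands[0], scheme)
        ct = detect_contacts(structure, ligands[0], scheme, hbonds=hb)
        got_hb = sorted((r.protein_residue.seq_num, r.ligand_atom.name) for r in hb)
        got_ct = sorted((r.protein_residue.seq_num, r.ligand_atom.name) for r in ct)
        if (got_hb != sorted((i, n) for i, n, _ in truth_hb)
                or got_ct != sorted((i, n) for i, n, _ in truth_ct)):
            raise FixtureError(
                f"infeasible geometry request: detected {got_hb}/{got_ct}, "
                f"planted {truth_hb}/{truth_ct}")

    if spec.rigid_motion is not None:
        rotation, translation = spec.rigid_motion
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for res in residues:
            for atom in res.atoms:
                atom.coords = rotation @ atom.coords + translation
        for atom in lig_atoms:
            atom.coords = rotation @ atom.coords + translation

    truth = {
        "structure_id": spec.structure_id,
        "chain_id": spec.chain_id,
        "sequence": sequence,
        "het_code": spec.het_code if lig_atoms else None,
        "hbonds": truth_hb,
        "contacts": truth_ct,
        "rigid_motion": (None if spec.rigid_motion is None else
                         (np.asarray(spec.rigid_motion[0]).tolist(),
                          np.asarray(spec.rigid_motion[1]).tolist())),
    }
    return write_pdb(structure), truth


def make_homolog(sequence: str, identity_target: float,
                 conserved_positions: Sequence[int] = (), seed: int = 0,
                 forced_classes: Optional[Dict[int, str]] = None) -> str:
    """Mutate a sequence to a target percent identity.

    Substitutions never touch ``conserved_positions`` (1-based).
    ``forced_classes`` maps positions to ``'similar'`` or ``'other'`` and
    guarantees those positions are substituted with an amino acid whose
    BLOSUM62 score against the original is positive resp. non-positive —
    this is how binding-site conservation classes are planted.
    """
    if not 0 < identity_target <= 100:
        raise FixtureError("identity_target must be in (0, 100]")
    length = len(sequence)
    n_sub = int(round(length * (1.0 - identity_target / 100.0)))
    realized = 100.0 * (length - n_sub) / length
    if abs(realized - identity_target) > 2.0:
        raise FixtureError(
            f"cannot realise {identity_target}% identity on a {length}-mer")
    forced_classes = dict(forced_classes or {})
    conserved = set(conserved_positions)
    if conserved & set(forced_classes):
        raise FixtureError("a position cannot be both conserved and forced")
    mutable = [i for i in range(1, length + 1)
               if i not in conserved and i not in forced_classes]
    if n_sub < len(forced_classes) or n_sub - len(forced_classes) > len(mutable):
        raise FixtureError(
            f"target {identity_target}% unreachable with "
            f"{len(conserved)} conserved and {len(forced_classes)} forced positions")

    rng = np.random.default_rng(seed)
    matrix = load_matrix("BLOSUM62")
    chosen = list(forced_classes) + list(
        rng.choice(mutable, size=n_sub - len(forced_classes), replace=False))

    out = list(sequence)
    for pos in chosen:
        orig = sequence[pos - 1]
        cls = forced_classes.get(pos)
        if cls == "similar":
            options = [a for a in AMINO_ACIDS if a != orig and matrix[orig, a] > 0]
        elif cls == "other":
            options = [a for a in AMINO_ACIDS if a != orig and matrix[orig, a] <= 0]
        else:
            options = [a for a in AMINO_ACIDS if a != orig]
        if not options:
            raise FixtureError(f"no {cls} substitution exists for {orig}")
        out[pos - 1] = str(rng.choice(options))
    return "".join(out)


# ---------------------------------------------------------------------------
# Molecule series
# ---------------------------------------------------------------------------

def _delete_atom(mol: MoleculeGraph, idx: int, name: str) -> MoleculeGraph:
    keep = [i for i in range(mol.n_atoms) if i != idx]
    remap = {old: new for new, old in enumerate(keep)}
    return MoleculeGraph(
        name=name,
        elements=tuple(mol.elements[i] for i in keep),
        bonds=tuple((remap[i], remap[j], order) for i, j, order in mol.bonds
                    if i != idx and j != idx))


def make_molecule_series(base: MoleculeGraph, edits: int) -> List[MoleculeGraph]:
    """``edits + 1`` graphs: the base, then successive single-atom deletions.

    Each step removes the lowest-index atom whose removal keeps the graph
    connected (degree-1 atoms first), so the series stays chemically sensible
    and its Tanimoto similarity to the base decreases monotonically:
    after k deletions it is exactly (n-k)/n for an n-atom base.
    """
    if edits >= base.n_atoms:
        raise FixtureError("edits must be smaller than the atom count")
    series = [base]
    current = base
    for k in range(1, edits + 1):
        degree = {i: len(current.neighbors(i)) for i in range(current.n_atoms)}
        leaf = [i for i in range(current.n_atoms) if degree[i] <= 1]
        candidates = leaf or list(range(current.n_atoms))
        chosen = None
        for idx in candidates:
            g = current.to_networkx()
            g.remove_node(idx)
            if g.number_of_nodes() == 0 or nx.is_connected(g):
                chosen = idx
                break
        if chosen is None:
            raise FixtureError("no deletable atom keeps the graph connected")
        current = _delete_atom(current, chosen, name=f"{base.name}_d{k}")
        series.append(current)
    return series


# ---------------------------------------------------------------------------
# Full synthetic study
# ---------------------------------------------------------------------------

#: base scaffolds used for the candidate/cognate chemistry
THYMINE_SMILES = "Cc1c[nH]c(=O)[nH]c1=O"
ADENINE_SMILES = "Nc1ncnc2[nH]cnc12"
SULFATE_SMILES = "[O-]S(=O)(=O)[O-]"


@dataclass
class FixtureSpec:
    """Study-level recipe: homolog identities, binding site, chemistry."""

    seed: int = 0
    n_residues: int = 250
    identities: Sequence[float] = (90.0, 60.0, 30.0)
    include_self: bool = False          # also put the query's own complex in
    domain_a: Tuple[int, int] = (1, 110)
    domain_b: Tuple[int, int] = (131, 250)
    hbond_sites_a: Sequence[int] = (30, 45, 60)
    contact_sites_a: Sequence[int] = (75, 90)
    hbond_sites_b: Sequence[int] = (150,)
    ligand_edits_step: int = 1


@dataclass
class StudyFixture:
    query_id: str
    query_seq: str
    structures: List[Structure]
    pdb_texts: Dict[str, str]
    annotations: List[DomainAnnotation]
    compounds: List[CompoundRecord]
    het_dictionary: Dict[str, MoleculeGraph]
    cognates: List[MoleculeGraph]
    truths: Dict[str, dict]
    conservation_plan: Dict[str, Dict[int, str]]


def make_study(spec: FixtureSpec = FixtureSpec()) -> StudyFixture:
    """A complete synthetic study with known ground truth.

    The query has two annotated domains separated by a 20-residue linker.
    One homolog complex is generated per requested identity; binding-site
    residues are kept identical in homologs above 80% identity, substituted
    with similar residues between 50 and 80%, and with dissimilar residues
    below 50%, so the conservation-weighted score decreases down the identity
    gradient while the planted interaction geometry is held fixed.  Ligands
    are successive single-atom edits of a thymine scaffold; source tables mix
    cognate-like, filter-passing and filter-failing records.
    """
    from .formats_io import read_pdb

    rng = np.random.default_rng(spec.seed)
    qseq = list(rng.choice(list(AMINO_ACIDS), size=spec.n_residues))
    binding_sites = (list(spec.hbond_sites_a) + list(spec.contact_sites_a)
                     + list(spec.hbond_sites_b))
    # binding-site residues need both similar and dissimilar substitution
    # partners under BLOSUM62; C, G and P have no positive off-diagonal entry
    substitutable = [a for a in AMINO_ACIDS if a not in "CGP"]
    for i in binding_sites:
        if qseq[i - 1] in "CGP":
            qseq[i - 1] = str(rng.choice(substitutable))
    qseq = "".join(qseq)
    interactions = (
        [PlantedInteraction(i, "hbond") for i in spec.hbond_sites_a]
        + [PlantedInteraction(i, "contact") for i in spec.contact_sites_a]
        + [PlantedInteraction(i, "hbond") for i in spec.hbond_sites_b])

    base = MoleculeGraph.from_smiles(THYMINE_SMILES, name="LG0")
    n_series = (1 if spec.include_self else 0) + len(spec.identities)
    series = make_molecule_series(
        base, edits=max(1, spec.ligand_edits_step * n_series))

    structures: List[Structure] = []
    pdb_texts: Dict[str, str] = {}
    truths: Dict[str, dict] = {}
    annotations: List[DomainAnnotation] = []
    het_dictionary: Dict[str, MoleculeGraph] = {}
    conservation_plan: Dict[str, Dict[int, str]] = {}

    identities = ([100.0] if spec.include_self else []) + list(spec.identities)
    for k, identity in enumerate(identities):
        sid = f"HM{k}"
        if identity >= 100.0:
            hseq = qseq
            plan: Dict[int, str] = {i: "identical" for i in binding_sites}
        elif identity > 80.0:
            hseq = make_homolog(qseq, identity, conserved_positions=binding_sites,
                                seed=spec.seed + 100 + k)
            plan = {i: "identical" for i in binding_sites}
        elif identity > 50.0:
            forced = {i: "similar" for i in binding_sites}
            hseq = make_homolog(qseq, identity, seed=spec.seed + 100 + k,
                                forced_classes=forced)
            plan = dict(forced)
        else:
            forced = {i: "other" for i in binding_sites}
            hseq = make_homolog(qseq, identity, seed=spec.seed + 100 + k,
                                forced_classes=forced)
            plan = dict(forced)
        conservation_plan[sid] = plan

        het = series[min(k, len(series) - 1)]
        het_code = f"LG{k}"
        het_dictionary[het_code] = MoleculeGraph(
            name=het_code, elements=het.elements, bonds=het.bonds)

        cspec = ComplexSpec(
            seed=spec.seed + 200 + k, n_residues=spec.n_residues, sequence=hseq,
            interactions=copy.deepcopy(interactions), structure_id=sid,
            het_code=het_code,
            rigid_motion=(None if k == 0 else
                          rigid_motion_from_seed(spec.seed + 300 + k)))
        text, truth = make_complex(cspec)
        truth["identity_target"] = identity
        pdb_texts[sid] = text
        truths[sid] = truth
        structures.append(read_pdb(text, structure_id=sid))
        annotations.append(DomainAnnotation(
            source_seq_id=f"{sid}_A", domain_id=f"{sid}d1",
            segments=[spec.domain_a], kind="cath_like"))
        annotations.append(DomainAnnotation(
            source_seq_id=f"{sid}_A", domain_id=f"{sid}d2",
            segments=[spec.domain_b], kind="cath_like"))

    thymine = MoleculeGraph.from_smiles(THYMINE_SMILES, name="cognate_thymine")
    adenine = MoleculeGraph.from_smiles(ADENINE_SMILES, name="CPD_ade")
    sulfate = MoleculeGraph.from_smiles(SULFATE_SMILES, name="CPD_so4")
    first_protein = "HM0_A"
    compounds = [
        CompoundRecord("CHEMBL_thy", "chembl",
                       MoleculeGraph.from_smiles(THYMINE_SMILES, "CHEMBL_thy"),
                       ic50_nM=50.0, xref_count=12,
                       assoc_protein_id=first_protein),
        CompoundRecord("CHEMBL_weak", "chembl",
                       MoleculeGraph.from_smiles(ADENINE_SMILES, "CHEMBL_weak"),
                       ic50_nM=500.0, xref_count=3,
                       assoc_protein_id=first_protein),
        CompoundRecord("CHEBI_ade", "chebi", adenine, xref_count=9,
                       assoc_protein_id=first_protein),
        CompoundRecord("CHEBI_so4", "chebi", sulfate, xref_count=30,
                       assoc_protein_id=first_protein),
        CompoundRecord("CHEBI_tiny", "chebi",
                       MoleculeGraph.from_smiles("O", "CHEBI_tiny"),
                       assoc_protein_id=first_protein),
        CompoundRecord("KEGG_thy", "kegg",
                       MoleculeGraph.from_smiles(THYMINE_SMILES, "KEGG_thy"),
                       assoc_protein_id=first_protein),
    ]
    return StudyFixture(
        query_id="QUERY", query_seq=qseq, structures=structures,
        pdb_texts=pdb_texts, annotations=annotations, compounds=compounds,
        het_dictionary=het_dictionary, cognates=[thymine], truths=truths,
        conservation_plan=conservation_plan)
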