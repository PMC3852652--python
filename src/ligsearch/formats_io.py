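"""Readers and writers for the formats the pipeline touches.

PDB-format structures (via gemmi), FASTA sequences (via Biopython),
SDF/TSV compound tables (via RDKit/pandas) and the ranked-result TSV.
Only the first model of a multi-model file is read; for alternate
conformations the highest-occupancy conformer is kept (ties: first seen).
Waters (HOH) are never treated as candidate ligands; every other HETATM
group — metals and ions included — is.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3
from rdkit import Chem

from .chem import ChemError, MoleculeGraph
from .sources import SOURCES, CompoundRecord

logger = logging.getLogger(__name__)

WATER_CODES = {"HOH"}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_ONE_TO_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
_ONE_TO_THREE["X"] = "UNK"

RESULT_COLUMNS = [
    "cluster_rank", "cluster_id", "ligand_id", "source",
    "score_achieved", "score_max", "structure_id", "chain_id",
    "assoc_identity_pct", "xref_count", "mol_weight", "heavy_atoms",
]


class PdbParseError(ValueError):
    """A malformed fixed-column record, reported with its line number."""


class EmptyStructureError(ValueError):
    """PDB content with no ATOM records."""


class FastaError(ValueError):
    """Invalid FASTA content (non-amino-acid residues, empty input)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_type: str
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.res_type)
        code = info.one_letter_code.upper() if info else "X"
        return code if code in _VALID_AA else "X"


@dataclass
class LigandInstance:
    structure_id: str
    het_code: str
    chain_id: str
    seq_num: int
    atoms: List[Atom]
    molecule: Optional[MoleculeGraph] = None

    def __post_init__(self):
        if not self.het_code:
            raise ValueError("ligand het_code must be non-empty")
        if not self.atoms:
            raise ValueError(f"ligand {self.het_code} has no atoms")

    @property
    def key(self) -> tuple:
        return (self.structure_id, self.het_code, self.chain_id, self.seq_num)

    @property
    def instance_id(self) -> str:
        return f"{self.structure_id}:{self.het_code}:{self.chain_id}:{self.seq_num}"


@dataclass
class Structure:
    id: str
    chains: Dict[str, List[Residue]]
    seqres: Dict[str, str] = field(default_factory=dict)
    ligands: List[LigandInstance] = field(default_factory=list)
    conect: Dict[int, List[int]] = field(default_factory=dict)

    def chain_sequence(self, chain_id: str) -> str:
        """SEQRES sequence when present, else the ATOM-derived sequence."""
        if chain_id in self.seqres and self.seqres[chain_id]:
            return self.seqres[chain_id]
        return "".join(r.one_letter for r in self.chains[chain_id])

    def residue(self, chain_id: str, seq_num: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.chains.get(chain_id, ()):
            if r.seq_num == seq_num and r.insertion_code == insertion_code:
                return r
        return None


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _validate_fixed_columns(text: str) -> bool:
    seen_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if rec == "ATOM":
            seen_atom = True
        if len(line.rstrip("\n")) < 54:
            raise PdbParseError(f"line {lineno}: record shorter than coordinate fields")
        try:
            int(line[6:11])
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(f"line {lineno}: malformed fixed-column record") from exc
    return seen_atom


def _pick_altlocs(res: gemmi.Residue) -> list:
    """Highest-occupancy conformer per atom name; ties broken first-seen."""
    best: Dict[str, gemmi.Atom] = {}
    order: List[str] = []
    for a in res:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def read_pdb(text: str, structure_id: Optional[str] = None) -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    Polymer residues come from ATOM records; each HETATM group sharing
    (het code, chain, residue number) becomes one :class:`LigandInstance`,
    waters excluded.  The per-chain sequence comes from SEQRES when present,
    otherwise it is derived from the ATOM residues.
    """
    if not _validate_fixed_columns(text):
        raise EmptyStructureError("no ATOM records in PDB content")
    st = gemmi.read_pdb_string(text)
    sid = structure_id or (st.name if st.name and st.name != "string" else "struct")
    model = st[0]

    chains: Dict[str, List[Residue]] = {}
    ligands: List[LigandInstance] = []
    for chain in model:
        for res in chain:
            atoms = [Atom(name=a.name, element=a.element.name,
                          coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                          serial=a.serial)
                     for a in _pick_altlocs(res)]
            icode = res.seqid.icode.strip()
            if res.het_flag == "H":
                if res.name in WATER_CODES:
                    continue
                ligands.append(LigandInstance(
                    structure_id=sid, het_code=res.name, chain_id=chain.name,
                    seq_num=res.seqid.num, atoms=atoms))
            else:
                chains.setdefault(chain.name, []).append(Residue(
                    chain_id=chain.name, seq_num=res.seqid.num,
                    insertion_code=icode, res_type=res.name, atoms=atoms))

    seqres: Dict[str, str] = {}
    for entity in st.entities:
        if entity.entity_type != gemmi.EntityType.Polymer or not entity.full_sequence:
            continue
        letters = ""
        for res_name in entity.full_sequence:
            info = gemmi.find_tabulated_residue(gemmi.Entity.first_mon(res_name))
            code = info.one_letter_code.upper() if info else "X"
            letters += code if code in _VALID_AA else "X"
        targets = entity.subchains or [entity.name]
        for chain_name in chains:
            if chain_name == entity.name or chain_name in targets:
                seqres[chain_name] = letters

    conect = {k: list(v) for k, v in st.conect_map.items()}
    return Structure(id=sid, chains=chains, seqres=seqres, ligands=ligands,
                     conect=conect)


def _format_atom_name(name: str) -> str:
    return name if len(name) >= 4 else f" {name:<3s}"


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to fixed-column PDB text."""
    lines: List[str] = []
    for chain_id, seq in structure.seqres.items():
        three = [_ONE_TO_THREE.get(c, "UNK") for c in seq]
        for i in range(0, len(three), 13):
            lines.append("SEQRES %3d %s %4d  %s" % (
                i // 13 + 1, chain_id, len(three), " ".join(three[i:i + 13])))
    serial = 0
    for chain_id in structure.chains:
        for res in structure.chains[chain_id]:
            for a in res.atoms:
                serial = a.serial if a.serial else serial + 1
                lines.append(
                    "ATOM  %5d %s %3s %s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
                    % (serial, _format_atom_name(a.name), res.res_type, chain_id,
                       res.seq_num, res.insertion_code or " ",
                       a.coords[0], a.coords[1], a.coords[2], 1.0, 0.0, a.element))
        lines.append("TER")
    for lig in structure.ligands:
        for a in lig.atoms:
            serial = a.serial if a.serial else serial + 1
            lines.append(
                "HETATM%5d %s %3s %s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
                % (serial, _format_atom_name(a.name), lig.het_code, lig.chain_id,
                   lig.seq_num, a.coords[0], a.coords[1], a.coords[2], 1.0, 0.0,
                   a.element))
    for serial_from in sorted(structure.conect):
        partners = structure.conect[serial_from]
        for i in range(0, len(partners), 4):
            lines.append("CONECT%5d" % serial_from +
                         "".join("%5d" % p for p in partners[i:i + 4]))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> List[Tuple[str, str]]:
    """Parse FASTA text into ``(id, sequence)`` pairs, validated and uppercased."""
    if not text.strip():
        raise FastaError("empty FASTA input")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        bad = set(seq) - _VALID_AA
        if bad:
            raise FastaError(
                f"record {rec.id!r}: invalid residue characters {sorted(bad)}")
        records.append((rec.id, seq))
    if not records:
        raise FastaError("no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Compound tables
# ---------------------------------------------------------------------------

def _record_from_fields(compound_id, smiles_or_mol, source, ic50, xref, protein_id,
                        has_bc=None) -> CompoundRecord:
    if isinstance(smiles_or_mol, MoleculeGraph):
        mol = smiles_or_mol
    else:
        mol = MoleculeGraph.from_smiles(smiles_or_mol, name=compound_id)
    rec = CompoundRecord(
        compound_id=compound_id, source=source, molecule=mol,
        ic50_nM=float(ic50) if ic50 not in (None, "") else None,
        xref_count=int(xref) if xref not in (None, "") else None,
        assoc_protein_id=protein_id or None)
    if has_bc is not None:
        rec.has_binding_constant = rec.has_binding_constant or bool(has_bc)
    return rec


def read_compound_table(text: str, dialect: str,
                        default_source: Optional[str] = None) -> List[CompoundRecord]:
    """Read an SDF or TSV compound table into :class:`CompoundRecord` objects.

    TSV columns: ``id, smiles, ic50_nM, xref_count, protein_id, source``
    (an optional ``has_binding_constant`` column marks non-IC50 binding
    constants).  SDF molecules carry the same fields as SD tags.  Records
    whose molecule cannot be parsed are skipped with a logged warning.
    """
    if dialect not in ("sdf", "tsv"):
        raise ValueError(f"dialect must be 'sdf' or 'tsv', got {dialect!r}")
    records: List[CompoundRecord] = []
    skipped = 0
    if dialect == "tsv":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
        for idx, row in df.iterrows():
            try:
                has_bc = row.get("has_binding_constant", "")
                records.append(_record_from_fields(
                    row["id"], row["smiles"], row.get("source", "") or default_source,
                    row.get("ic50_nM", ""), row.get("xref_count", ""),
                    row.get("protein_id", ""),
                    has_bc.strip().lower() in ("1", "true", "yes") if has_bc else None))
            except (ChemError, ValueError) as exc:
                skipped += 1
                logger.warning("compound row %d skipped: %s", idx + 1, exc)
    else:
        supplier = Chem.ForwardSDMolSupplier(io.BytesIO(text.encode()), sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("SDF molecule %d skipped: unparsable connection table",
                               idx + 1)
                continue
            def prop(name):
                return mol.GetProp(name) if mol.HasProp(name) else ""
            cid = prop("id") or (mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx+1}")
            try:
                records.append(_record_from_fields(
                    cid, MoleculeGraph.from_rdkit(mol, name=cid),
                    prop("source") or default_source,
                    prop("ic50_nM"), prop("xref_count"), prop("protein_id")))
            except (ChemError, ValueError) as exc:
                skipped += 1
                logger.warning("SDF molecule %d skipped: %s", idx + 1, exc)
    if skipped:
        logger.warning("%d compound record(s) skipped while reading %s table",
                       skipped, dialect)
    return records


# ---------------------------------------------------------------------------
# Results TSV
# ---------------------------------------------------------------------------

def _fmt(value, spec=None):
    if value is None:
        return ""
    if spec:
        return format(value, spec)
    return str(value)


def write_results_tsv(result, destination) -> None:
    """Write a ranked result as TSV, one row per candidate in ranked order."""
    rows = []
    for cluster in result.clusters:
        for cand in cluster.members:
            rows.append({
                "cluster_rank": cluster.rank,
                "cluster_id": cluster.cluster_id,
                "ligand_id": cand.ligand_id,
                "source": cand.source,
                "score_achieved": _fmt(cand.score.achieved if cand.score else None),
                "score_max": _fmt(cand.score.maximum if cand.score else None),
                "structure_id": _fmt(cand.structure_id),
                "chain_id": _fmt(cand.chain_id),
                "assoc_identity_pct": _fmt(cand.assoc_identity_pct, ".1f"),
                "xref_count": _fmt(cand.xref_count),
                "mol_weight": _fmt(cand.mol_weight, ".2f"),
                "heavy_atoms": _fmt(cand.heavy_atoms),
            })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if hasattr(destination, "write"):
        df.to_csv(destination, sep="\t", index=False)
    else:
        with open(destination, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)


def read_results_tsv(source) -> pd.DataFrame:
    """Read back a results TSV (convenience for round-trips and evaluation)."""
    if hasattr(source, "read"):
        return pd.read_csv(source, sep="\t", dtype=str).fillna("")
    return pd.read_csv(io.StringIO(source) if "\t" in source or "\n" in source
                       else source, sep="\t", dtype=str).fillna("")
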