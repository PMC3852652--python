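"""End-to-end candidate-ligand prediction and ranking.

Given a query sequence (or a structure, from which the sequence is
extracted), a library of protein–ligand complexes, domain annotations for
the library chains and compound-source tables, the pipeline:

1. ranks the query against the library chains and keeps the top 20 homologs;
2. gathers source compounds associated with those homologs, applies the
   per-source filters and removes duplicates;
3. partitions the query into predicted domains from the homolog annotations;
4. searches each predicted domain against the full-chain + split-domain
   sequence database, takes the best match as the reference structure and
   superposes the remaining hits onto it;
5. detects each PDB ligand's hydrogen bonds and nonbonded contacts, scores
   them by binding-site conservation relative to the query, and merges the
   per-domain scores of ligands that span domains;
6. clusters all candidates by MCS Tanimoto similarity (cutoff 0.4) and ranks
   clusters by the best PDB ligand score, listing source-only compounds by
   associated-protein identity and cross-reference count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from . import chem, sources
from .align import (AlignmentPair, SequenceDbEntry, build_query_anchored_msa,
                    build_sequence_db, rank_hits)
from .chem import Cluster, MoleculeGraph
from .domain_partition import DomainAnnotation, partition_query
from .formats_io import LigandInstance, Structure, write_results_tsv
from .interactions import (LigandScore, ScoringScheme, classify_conservation,
                           detect_contacts, detect_hbonds, merge_domain_scores,
                           score_ligand)
from .superpose import SuperposeError, iterative_superpose

logger = logging.getLogger(__name__)

#: minimum predicted-domain sequence length worth searching
MIN_DOMAIN_SEARCH_LEN = 10


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Tunable thresholds; the defaults are the method's published constants."""

    top_n_hits: int = 20
    rmsd_cutoff: float = 12.0           # Å, iterative-superposition stop
    cluster_cutoff: float = 0.4         # min similarity between cluster members
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix_name: str = "BLOSUM62"
    unknown_domain_min: int = 100       # residues
    min_mapped_domain: int = 20         # residues
    min_query_len: int = 30
    max_ic50_nM: float = 100.0
    chebi_min_atoms: int = 4
    chebi_min_weight: float = 50.0
    mcs_size_limit: int = 60
    mcs_time_budget_s: float = 10.0
    random_seed: int = 0

    def __post_init__(self):
        for name in ("top_n_hits", "rmsd_cutoff", "cluster_cutoff", "gap_open",
                     "gap_extend", "unknown_domain_min", "min_mapped_domain",
                     "min_query_len", "max_ic50_nM", "chebi_min_atoms",
                     "chebi_min_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def align_kwargs(self) -> dict:
        return dict(matrix=self.matrix_name, gap_open=self.gap_open,
                    gap_extend=self.gap_extend)

    @property
    def mcs_kwargs(self) -> dict:
        return dict(size_limit=self.mcs_size_limit,
                    time_budget_s=self.mcs_time_budget_s)


@dataclass
class Candidate:
    """One candidate ligand in the ranked output."""

    ligand_id: str
    source: str                     # 'pdb' | 'chembl' | 'chebi' | 'kegg'
    molecule: Optional[MoleculeGraph] = None
    score: Optional[LigandScore] = None
    structure_id: Optional[str] = None
    chain_id: Optional[str] = None
    assoc_identity_pct: Optional[float] = None
    xref_count: Optional[int] = None
    mol_weight: Optional[float] = None
    heavy_atoms: Optional[int] = None

    @property
    def member_key(self) -> str:
        return f"{self.source}:{self.ligand_id}"


@dataclass
class RankedResult:
    query_id: str
    clusters: List[Cluster] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)
    config: Optional[PipelineConfig] = None

    @property
    def candidates(self) -> List[Candidate]:
        return [cand for cl in self.clusters for cand in cl.members]

    def write_tsv(self, destination) -> None:
        write_results_tsv(self, destination)


# ---------------------------------------------------------------------------
# Ranking rules
# ---------------------------------------------------------------------------

def _none_low(value) -> float:
    return -1.0 if value is None else float(value)


def order_within_cluster(cluster: Cluster) -> List[Candidate]:
    """PDB ligands by interaction score, then source hits by identity/xrefs."""
    pdb = [c for c in cluster.members if c.source == "pdb"]
    rest = [c for c in cluster.members if c.source != "pdb"]
    pdb.sort(key=lambda c: (-c.score.achieved if c.score else 0,
                            -c.score.maximum if c.score else 0, c.ligand_id))
    rest.sort(key=lambda c: (-_none_low(c.assoc_identity_pct),
                             -_none_low(c.xref_count), c.ligand_id))
    return pdb + rest


def rank_clusters(clusters: Sequence[Cluster]) -> List[Cluster]:
    """Order clusters by their best PDB ligand score.

    Clusters without any PDB member follow the scored ones, ordered by the
    highest member associated-protein identity, then cross-reference count,
    then cluster id.  Members are ordered within each cluster as well, and
    ranks are assigned 1..n.
    """
    prepared = []
    for cl in clusters:
        members = order_within_cluster(cl)
        pdb_scores = [c.score.achieved for c in members
                      if c.source == "pdb" and c.score is not None]
        best = max(pdb_scores) if pdb_scores else None
        prepared.append(Cluster(cluster_id=cl.cluster_id, members=members,
                                best_pdb_score=best))
    prepared.sort(key=lambda cl: (
        (0, -cl.best_pdb_score, cl.cluster_id) if cl.best_pdb_score is not None
        else (1, -max((_none_low(c.assoc_identity_pct) for c in cl.members),
                      default=-1.0),
              -max((_none_low(c.xref_count) for c in cl.members), default=-1.0),
              cl.cluster_id)))
    for rank, cl in enumerate(prepared, start=1):
        cl.rank = rank
    return prepared


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------

def _query_sequence(query, min_len: int) -> Tuple[str, str]:
    if isinstance(query, Structure):
        if not query.chains:
            raise PipelineError("query structure has no polymer chains")
        first_chain = next(iter(query.chains))
        qid, qseq = query.id, query.chain_sequence(first_chain)
    else:
        qid, qseq = query
    if len(qseq) < min_len:
        raise PipelineError(
            f"query sequence length {len(qseq)} below minimum {min_len}")
    return qid, qseq


def _molecule_from_ligand(lig: LigandInstance, structure: Structure,
                          het_dictionary: Optional[Mapping] = None
                          ) -> MoleculeGraph:
    """Molecule graph for a PDB ligand: het dictionary first, CONECT fallback."""
    if het_dictionary and lig.het_code in het_dictionary:
        entry = het_dictionary[lig.het_code]
        if isinstance(entry, MoleculeGraph):
            return replace(entry, name=lig.het_code) if entry.name != lig.het_code else entry
        return MoleculeGraph.from_smiles(entry, name=lig.het_code)
    heavy = [a for a in lig.atoms if a.element != "H"]
    serial_to_idx = {a.serial: i for i, a in enumerate(heavy)}
    bonds = []
    for s, partners in structure.conect.items():
        if s in serial_to_idx:
            bonds.extend((serial_to_idx[s], serial_to_idx[p], 1.0)
                         for p in partners if p in serial_to_idx)
    if not bonds and len(heavy) > 1:
        logger.warning("ligand %s has no het-dictionary entry and no CONECT "
                       "records; using a bondless graph", lig.instance_id)
    return MoleculeGraph(name=lig.het_code,
                         elements=tuple(a.element for a in heavy),
                         bonds=tuple(bonds))


def _residue_for_entry_pos(entry: SequenceDbEntry, structure: Structure, pos: int):
    chain_pos = entry.entry_pos_to_chain_pos(pos)
    residues = structure.chains.get(entry.chain_id, [])
    if 1 <= chain_pos <= len(residues):
        return residues[chain_pos - 1]
    return None


def _entry_pos_of_residue(entry: SequenceDbEntry, structure: Structure,
                          residue) -> Optional[int]:
    residues = structure.chains.get(residue.chain_id, [])
    if residue.chain_id != entry.chain_id:
        return None
    try:
        chain_pos = residues.index(residue) + 1
    except ValueError:
        return None
    off = 0
    for s, e in entry.segments:
        if s <= chain_pos <= e:
            return off + (chain_pos - s) + 1
        off += e - s + 1
    return None


def attach_source_identities(records: Sequence[sources.CompoundRecord],
                             hits: Sequence[AlignmentPair],
                             entries: Mapping[str, SequenceDbEntry]
                             ) -> List[sources.CompoundRecord]:
    """Keep records associated with a ranked homolog; stamp its identity."""
    best_by_protein: Dict[str, float] = {}
    for p in hits:
        entry = entries[p.hit_id]
        for key in (entry.entry_id, entry.parent_structure_id):
            cur = best_by_protein.get(key)
            if cur is None or p.identity_pct > cur:
                best_by_protein[key] = p.identity_pct
    kept = []
    for r in records:
        identity = best_by_protein.get(r.assoc_protein_id)
        if identity is None:
            continue
        r.assoc_identity_pct = identity
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(query, structures: Sequence[Structure],
                 annotations: Sequence[DomainAnnotation] = (),
                 compounds: Sequence[sources.CompoundRecord] = (),
                 config: Optional[PipelineConfig] = None,
                 het_dictionary: Optional[Mapping] = None) -> RankedResult:
    """Run the full prediction workflow; see the module docstring."""
    config = config or PipelineConfig()
    scheme = config.scheme
    log: List[str] = []
    qid, qseq = _query_sequence(query, config.min_query_len)
    st_by_id = {st.id: st for st in structures}

    db = build_sequence_db(structures, annotations)
    entry_by_id = {e.entry_id: e for e in db}
    full_chain = [e for e in db if e.kind == "full_chain"]
    hits = rank_hits(qseq, full_chain, n=config.top_n_hits, query_id=qid,
                     **config.align_kwargs)
    log.append(f"homolog search: {len(hits)} hit(s) among {len(full_chain)} chains")

    # -- source compounds -----------------------------------------------
    associated = attach_source_identities(list(compounds), hits, entry_by_id)
    by_source = {s: [r for r in associated if r.source == s]
                 for s in sources.SOURCES}
    filtered = sources.dedup_union(
        sources.filter_chembl(by_source["chembl"], max_ic50_nM=config.max_ic50_nM),
        sources.filter_chebi(by_source["chebi"], min_atoms=config.chebi_min_atoms,
                             min_weight=config.chebi_min_weight),
        by_source["kegg"])
    log.append(f"compound sources: {len(associated)} associated record(s), "
               f"{len(filtered)} after filters and dedup")

    # -- domain partition ------------------------------------------------
    anns_by_seq: Dict[str, List[DomainAnnotation]] = {}
    for ann in annotations:
        anns_by_seq.setdefault(ann.source_seq_id, []).append(ann)
    ranked = [(p, anns_by_seq.get(p.hit_id, [])) for p in hits]
    partition = partition_query(len(qseq), ranked,
                                unknown_min=config.unknown_domain_min,
                                min_mapped=config.min_mapped_domain)
    log.append("domain partition: " + "; ".join(
        f"{d.label}({d.kind}) " + ",".join(f"{s}-{e}" for s, e in d.segments)
        for d in partition.assigned))

    # -- per-domain structure search, superposition and scoring ----------
    lig_scores: Dict[tuple, List[LigandScore]] = {}
    lig_identity: Dict[tuple, float] = {}
    lig_instances: Dict[tuple, Tuple[LigandInstance, Structure]] = {}

    for dom in partition.assigned:
        dom_seq = "".join(qseq[s - 1:e] for s, e in dom.segments)
        if len(dom_seq) < MIN_DOMAIN_SEARCH_LEN:
            continue
        dom_hits_all = rank_hits(dom_seq, db, n=config.top_n_hits,
                                 query_id=f"{qid}|{dom.label}",
                                 **config.align_kwargs)
        dom_hits, seen = [], set()
        for p in dom_hits_all:       # one entry per structure chain: best first
            entry = entry_by_id[p.hit_id]
            key = (entry.parent_structure_id, entry.chain_id)
            if key not in seen:
                seen.add(key)
                dom_hits.append(p)
        if not dom_hits:
            log.append(f"domain {dom.label}: no structure hits")
            continue
        ref_pair = dom_hits[0]
        ref_entry = entry_by_id[ref_pair.hit_id]
        ref_structure = st_by_id[ref_entry.parent_structure_id]
        log.append(f"domain {dom.label}: {len(dom_hits)} structure hit(s), "
                   f"reference {ref_entry.entry_id}")
        msa = build_query_anchored_msa(dom_hits)

        for pair in dom_hits:
            entry = entry_by_id[pair.hit_id]
            structure = st_by_id[entry.parent_structure_id]
            if pair is not ref_pair:
                res_pairs = []
                for ref_pos, hit_pos in msa.equivalences(ref_pair.hit_id,
                                                         pair.hit_id):
                    ref_res = _residue_for_entry_pos(ref_entry, ref_structure,
                                                     ref_pos)
                    mob_res = _residue_for_entry_pos(entry, structure, hit_pos)
                    if ref_res is not None and mob_res is not None:
                        res_pairs.append((ref_res, mob_res))
                try:
                    sup = iterative_superpose(ref_structure, structure,
                                              res_pairs,
                                              cutoff=config.rmsd_cutoff)
                    log.append(f"superposed {entry.entry_id} onto "
                               f"{ref_entry.entry_id}: rmsd {sup.rmsd:.2f} A over "
                               f"{len(sup.retained)} residues"
                               + ("" if sup.converged else " (not converged)"))
                except SuperposeError as exc:
                    log.append(f"superposition of {entry.entry_id} skipped: {exc}")

            query_to_hit = msa.rows[pair.hit_id]
            for lig in structure.ligands:
                hbonds = detect_hbonds(structure, lig, scheme)
                contacts = detect_contacts(structure, lig, scheme, hbonds=hbonds)
                if not hbonds and not contacts:
                    continue
                for record in hbonds + contacts:
                    hit_pos = _entry_pos_of_residue(entry, structure,
                                                    record.protein_residue)
                    classify_conservation(record, hit_pos, query_to_hit,
                                          dom_seq, entry.sequence,
                                          matrix=config.matrix_name)
                score = score_ligand(lig, hbonds, contacts, scheme)
                lig_scores.setdefault(lig.key, []).append(score)
                lig_instances[lig.key] = (lig, structure)
                prev = lig_identity.get(lig.key)
                if prev is None or pair.identity_pct > prev:
                    lig_identity[lig.key] = pair.identity_pct

    merged = {key: merge_domain_scores(scores, scheme)
              for key, scores in lig_scores.items()}

    # -- unique PDB candidates (best-scoring instance per het code) ------
    best_by_het: Dict[str, tuple] = {}
    for key, score in merged.items():
        het = key[1]
        rank_key = (-score.achieved, -score.maximum, key[0], key[2], key[3])
        if het not in best_by_het or rank_key < best_by_het[het][0]:
            best_by_het[het] = (rank_key, key, score)

    candidates: List[Candidate] = []
    for het in sorted(best_by_het):
        _, key, score = best_by_het[het]
        lig, structure = lig_instances[key]
        mol = _molecule_from_ligand(lig, structure, het_dictionary)
        props = chem.properties(mol)
        candidates.append(Candidate(
            ligand_id=het, source="pdb", molecule=mol, score=score,
            structure_id=key[0], chain_id=key[2],
            assoc_identity_pct=lig_identity[key],
            mol_weight=props.mol_weight, heavy_atoms=props.heavy_atoms))
    for r in filtered:
        props = chem.properties(r.molecule)
        candidates.append(Candidate(
            ligand_id=r.compound_id, source=r.source, molecule=r.molecule,
            assoc_identity_pct=r.assoc_identity_pct, xref_count=r.xref_count,
            mol_weight=props.mol_weight, heavy_atoms=props.heavy_atoms))
    log.append(f"candidates: {len(best_by_het)} unique PDB ligand(s), "
               f"{len(filtered)} source compound(s)")

    if not candidates:
        log.append("no candidates found")
        return RankedResult(query_id=qid, clusters=[], provenance=log,
                            config=config)

    # -- clustering and ranking ------------------------------------------
    by_key = {c.member_key: c for c in candidates}
    mols = [replace(c.molecule, name=c.member_key) for c in candidates]
    raw_clusters = chem.cluster_molecules(mols, cutoff=config.cluster_cutoff,
                                          **config.mcs_kwargs)
    for cl in raw_clusters:
        cl.members = [by_key[mid] for mid in cl.members]
    clusters = rank_clusters(raw_clusters)
    log.append(f"clustering: {len(clusters)} cluster(s) at cutoff "
               f"{config.cluster_cutoff}")
    return RankedResult(query_id=qid, clusters=clusters, provenance=log,
                        config=config)


# ---------------------------------------------------------------------------
# Validation-style evaluation against cognate ligands
# ---------------------------------------------------------------------------

@dataclass
class CognateMatch:
    cognate: str
    best_similarity: float
    best_candidate: Optional[str] = None
    co_members: int = 0     # other molecules clustered with the cognate


@dataclass
class CognateEvaluation:
    matches: List[CognateMatch]
    n_ge_09: int = 0
    n_ge_08: int = 0
    n_ge_07: int = 0
    n_with_co_members: int = 0

    def __post_init__(self):
        self.n_ge_09 = sum(1 for m in self.matches if m.best_similarity >= 0.9)
        self.n_ge_08 = sum(1 for m in self.matches if m.best_similarity >= 0.8)
        self.n_ge_07 = sum(1 for m in self.matches if m.best_similarity >= 0.7)
        self.n_with_co_members = sum(1 for m in self.matches if m.co_members > 0)


def evaluate_against_cognates(result: RankedResult,
                              cognates: Sequence[MoleculeGraph],
                              cluster_cutoff: float = 0.4,
                              **mcs_kwargs) -> CognateEvaluation:
    """Compare returned candidates against known binders of the query.

    For each cognate molecule the best Tanimoto similarity over the returned
    candidates is recorded, and the cognate is co-clustered with the
    candidate pool to count how many returned molecules share its cluster.
    """
    if not cognates:
        raise ValueError("cognates must be non-empty")
    pool = [c for c in result.candidates if c.molecule is not None]
    mols = [replace(c.molecule, name=c.member_key) for c in pool]
    base_sim = chem.similarity_matrix(mols, **mcs_kwargs) if mols else []
    matches = []
    for cog in cognates:
        sims = [chem.similarity(cog, m, **mcs_kwargs).value for m in mols]
        best = max(sims) if sims else 0.0
        best_candidate = mols[sims.index(best)].name if sims else None
        co_members = 0
        if mols:
            ids = [m.name for m in mols] + ["__cognate__"]
            ext = [row + [sims[i]] for i, row in enumerate(base_sim)]
            ext.append(sims + [1.0])
            for cl in chem.cluster_from_matrix(ids, ext, cutoff=cluster_cutoff):
                if "__cognate__" in cl.members:
                    co_members = len(cl.members) - 1
                    break
        matches.append(CognateMatch(cognate=cog.name, best_similarity=best,
                                    best_candidate=best_candidate,
                                    co_members=co_members))
    return CognateEvaluation(matches=matches)
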