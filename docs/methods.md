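# Methods

## The problem and the approach

Crystallographers frequently need candidate small molecules to co-crystallise
with a protein of interest. `ligsearch` automates the knowledge-based route:
instead of docking, it transfers binding information from homologous
protein–ligand complexes and from curated protein-to-compound associations,
then clusters and ranks the pooled candidates so the most promising
chemistry rises to the top. The method is sequence-driven, so it applies
equally to proteins with and without a solved structure.

The pipeline has six stages:

1. **Homolog search.** The query sequence is aligned against every polymer
   chain in the structure library with Smith–Waterman local alignment
   (BLOSUM62, affine gaps), and the top 20 hits are kept.
2. **Compound sources.** Compounds associated with those homologs in
   ChEMBL-, ChEBI- and KEGG-style tables are collected. ChEMBL records must
   carry a binding constant, and an IC50, when present, must be ≤ 100 nM
   (strictly greater values are excluded). ChEBI records need ≥ 4 atoms
   (implicit hydrogens counted) and ≥ 50 Da. KEGG records pass unfiltered.
   The union is deduplicated by exact molecular-graph isomorphism, keeping
   the record with the most metadata (binding constant ≻ cross-reference
   count ≻ first seen).
3. **Domain partition.** Homolog domain annotations (CATH-like structural
   domains, Pfam-like sequence domains) are transferred onto the query
   through the pairwise alignments and accepted greedily, best hit first,
   with a strict no-overlap rule. Each annotation segment maps to the
   minimal query interval covering its aligned positions; fragments under
   20 mapped residues are dropped as noise. Unassigned runs longer than 100
   residues become domains of unknown type; internal linkers are split at
   their midpoint between the flanking domains (odd residue to the
   N-terminal side); terminal runs merge into the single adjacent domain.
   The result is always an exact partition of the query.
4. **Structure search and superposition.** Each predicted domain is searched
   against a sequence database holding every full chain *and* every
   annotated domain as its own entry — split domains (e.g. residues 6–57 ∪
   177–331 of a two-segment domain) are searchable as one concatenated
   sequence. The best-scoring hit is the reference; every other hit is
   superposed onto it over the main-chain atoms (N, CA, C, O) of residues
   aligned to the same query position. The least-squares (Kabsch) fit is
   iterated, trimming the worst 10% of residue pairs per round (at least
   one, never below three retained), until the RMSD falls below 12 Å.
5. **Interaction scoring.** For every ligand in a hit complex, hydrogen
   bonds (polar heavy atoms N/O/S within 3.35 Å) and nonbonded contacts
   (heavy atoms within 3.9 Å, at most one per protein residue, and none for
   residues already hydrogen-bonded) are detected in the ligand's own
   complex. Each interaction is weighted by the conservation of the
   contacted residue relative to the query through the alignment:

   | conservation      | H-bond | contact |
   |-------------------|-------:|--------:|
   | identical residue |      3 |       2 |
   | similar (matrix > 0) | 2   |       1 |
   | other             |      1 |       0 |
   | gap (unaligned)   |     −1 |      −1 |

   The score is reported as *achieved*/*maximum*, the maximum re-scoring the
   same interactions as if every residue were identical, so a hit identical
   to the query achieves its ceiling. Ligands that touch several domains are
   re-scored on the union of their per-domain records with each protein
   residue counted once (hydrogen-bond records beat contact records on
   collision).
6. **Clustering and ranking.** All candidates — unique PDB ligands plus the
   filtered source compounds — are clustered by maximum-common-subgraph
   (MCS) Tanimoto similarity, |MCS| / (|A| + |B| − |MCS|) over heavy atoms,
   with complete-linkage agglomeration at cutoff 0.4, so even the two most
   distant members of a cluster are at least 40% similar. Clusters are
   ranked by their best PDB ligand score; within a cluster, PDB ligands sort
   by score and source compounds follow, ordered by associated-protein
   identity and then cross-reference count. Clusters with no PDB member
   follow the scored clusters under the same identity/xref ordering.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_n_hits` | 20 | homologs kept from the chain search |
| `matrix_name`, `gap_open`, `gap_extend` | BLOSUM62, 11, 1 | alignment model; a gap of length *k* costs 11 + *k* |
| `hbond_max_dist` | 3.35 Å | polar heavy-atom distance for a hydrogen bond |
| `contact_max_dist` | 3.9 Å | heavy-atom distance for a nonbonded contact |
| `rmsd_cutoff` | 12 Å | iterative-superposition stopping RMSD |
| `cluster_cutoff` | 0.4 | minimum intra-cluster pairwise similarity |
| `unknown_domain_min` | 100 | unassigned run length that becomes an unknown domain |
| `min_mapped_domain` | 20 | smallest mapped domain fragment kept |
| `max_ic50_nM` | 100 | ChEMBL potency filter |
| `chebi_min_atoms`, `chebi_min_weight` | 4, 50 Da | ChEBI size filters |
| `mcs_size_limit`, `mcs_time_budget_s` | 60, 10 | exact-MCS bounds; beyond them the best mapping found is returned flagged non-exact |

The 12 Å RMSD threshold is unusually permissive for a superposition
acceptance criterion; it is kept as the method's stated default and exposed
in `PipelineConfig` for users who prefer a tighter value.

## Numerical and design choices

- **Alignment engine.** One Smith–Waterman engine (Biopython's
  `PairwiseAligner`, local mode) models the heuristic search tools a
  production deployment would use; it is exact, deterministic (ties resolved
  by the aligner's fixed traceback preference, hits re-sorted by score then
  entry id), and verified against a brute-force gap-length-enumeration DP.
  Percent identity is identical columns over aligned (non-gap) columns,
  reported to one decimal.
- **Hydrogen bonds are distance-only.** Deposited structures usually lack
  hydrogens, so no angle term is applied; thresholds follow common
  HBPLUS/LigPlot-style practice.
- **MCS definition.** Connected *induced* common subgraph under element and
  bond-order matching (aromatic bonds are their own order), found by a
  McGregor-style branch-and-bound with candidate-pair exclusion. Similarity
  1.0 is attained exactly for isomorphic molecules. Charges are ignored.
  Single-atom species (metals, ions) cluster like any other graph.
- **Clustering tie-break.** When two merges share the same complete-linkage
  value, the pair whose combined member-id tuple is lexicographically
  smallest merges first, making the clustering reproducible to the byte.
- **Altloc handling.** The highest-occupancy conformer per atom is kept,
  ties first-seen. Waters (HOH) are never candidates; every other HETATM
  group is, metals included. Only the first model of a multi-model file is
  read.
- **Molecular properties.** Molecules parsed from SMILES/SDF use RDKit
  descriptors (MolWt, logP, TPSA). Bare graphs (e.g. ligands reconstructed
  from CONECT records) fall back to a mass sum with implicit hydrogens from
  default valences; for aromatic nitrogens this undercounts N–H hydrogens by
  design of the valence convention, and logP/PSA are reported absent.
- **PDB ligand chemistry.** Candidate molecule graphs come from a het-code
  dictionary (SMILES per chemical component) when provided — the analogue of
  the PDB chemical-component dictionary — else from CONECT records with
  single bonds, else as a bondless atom set (logged).

## The synthetic-data generator

Real deposited complexes cannot ship with the package, so every stage is
exercised on generated fixtures with known ground truth:

- **Complexes** are extended chains (3.8 Å CA spacing, fixed N/C/O offsets).
  Planted hydrogen bonds place a ligand oxygen below the target residue's
  backbone O; planted contacts place a ligand carbon above the CA. The
  directions guarantee no unintended atom falls within the detection
  thresholds, and the generator runs the detectors to verify the planted set
  is recovered exactly before returning. Rigid motions (seeded random
  rotation + translation) are applied to whole complexes to exercise
  superposition.
- **Homologs** are substitution-only mutants at a target percent identity.
  Binding-site conservation classes are planted by substitution-matrix sign:
  identical above 80% identity, similar (BLOSUM62 > 0) between 50 and 80%,
  dissimilar below 50% — so the conservation-weighted score must decrease
  down the identity gradient while the geometry stays fixed.
- **Chemistry** derives candidate ligands from a 9-heavy-atom pyrimidinone
  scaffold by successive single-atom deletions, giving exact expected
  Tanimoto values ((n−k)/n after k deletions); a purine and a sulfate
  provide out-of-family compounds for the source tables.

The default study is a 250-residue query with two annotated domains
separated by a 20-residue linker, four homolog complexes at 100/90/60/30%
identity, six planted interactions (three hydrogen bonds in domain A, two
contacts in domain A, one hydrogen bond in domain B — so the ligand spans
domains and exercises score merging), and six source records spanning the
filter semantics. These sizes keep the full suite and the acceptance script
in seconds while covering every rule of the method.

What the generator does **not** emulate: realistic folds and side chains
(only backbone atoms exist), alignment gaps caused by insertions/deletions
(homologs are substitution-only; gapped conservation classes are tested via
hand-built alignments), crystallographic noise, multiple chains per entry,
and genuinely hard MCS instances. Passing tests therefore demonstrate the
correctness of the rules and arithmetic, not retrieval performance on real
databases.

## Known limitations

- Interaction geometry is distance-only; π-stacking, salt-bridge and
  water-mediated interactions are out of scope.
- The exact-MCS search is exponential in the worst case; beyond the size
  limit or time budget the result is a flagged lower bound, which can move
  borderline cluster memberships near the 0.4 cutoff.
- SEQRES-to-coordinate mapping assumes the residues present in ATOM records
  run parallel to the SEQRES sequence; entries with long unmodelled internal
  stretches would need an explicit alignment of the two.
- PDB text stores coordinates to 3 decimals; round-tripping a structure
  through text caps geometric agreement at ~1e-3 Å (superposition tests that
  check 1e-6 rotation recovery apply motions in memory).
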