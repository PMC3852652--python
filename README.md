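# ligsearch

Knowledge-based prediction and ranking of candidate ligands for a query
protein. Given a protein sequence (or a PDB-format structure, from which the
sequence is extracted), a local library of protein–ligand complexes with
domain annotations, and compound tables exported from protein-to-compound
resources (ChEMBL/ChEBI/KEGG style), `ligsearch` returns clusters of
candidate small molecules ranked by how well their known binding is expected
to transfer to the query. It is aimed at structural biologists assembling
co-crystallisation trials and at anyone triaging "what might this protein
bind?" from sequence alone.

## The method in brief

The query is aligned (Smith–Waterman, BLOSUM62, affine gaps) against every
library chain; the top 20 homologs define both the compound-source pool and
a domain partition of the query, transferred from the homologs' CATH/Pfam-
style annotations. Each predicted domain is searched against a database of
full-chain *and* per-domain sequences (so split domains are matched), hits
are superposed onto the best match by iterated Kabsch fitting with outlier
trimming, and every ligand in a hit complex is scored by the interactions it
makes, weighted by binding-site conservation. With `res(h)` the protein
residue contacted in the hit and `res(q)` its aligned query residue:

```
score = Σ_hbonds  w_hb(res)  + Σ_contact residues  w_nb(res)

w_hb  = 3 / 2 / 1 / −1   (identical / similar / other / gap)
w_nb  = 2 / 1 / 0 / −1
```

reported as `achieved/maximum`, where the maximum assumes every contacted
residue were identical — a hit identical to the query scores, say, `21/21`
at 100% identity. Candidates are then clustered by maximum-common-subgraph
Tanimoto similarity (complete linkage at 0.4, so all cluster members are at
least 40% similar) and clusters are ranked by their best PDB ligand score;
compounds that come only from the source tables are listed after the
structurally scored ligands, ordered by the identity of their associated
protein and their cross-reference count.

See `docs/methods.md` for the full model, parameter table and design notes.

## Worked example

The package ships a synthetic-study generator with known ground truth (a
250-residue two-domain query, homolog complexes at 100/90/60/30% identity
with the same planted binding-site geometry, and mixed compound tables):

```python
from ligsearch.fixtures import FixtureSpec, make_study
from ligsearch.pipeline import run_pipeline, evaluate_against_cognates

study = make_study(FixtureSpec(seed=1, include_self=True))
result = run_pipeline((study.query_id, study.query_seq), study.structures,
                      study.annotations, study.compounds,
                      het_dictionary=study.het_dictionary)
for cl in result.clusters:
    print(f"cluster {cl.rank} (best PDB score {cl.best_pdb_score}):")
    for c in cl.members:
        score = c.score.as_fraction if c.score else "-"
        print(f"  {c.member_key:<22s} score {score:<7s} identity "
              f"{c.assoc_identity_pct or '-'}")
```

prints

```
cluster 1 (best PDB score 16):
  pdb:LG0                score 16/16   identity 100.0
  pdb:LG1                score 16/16   identity 91.5
  pdb:LG2                score 10/16   identity 64.6
  pdb:LG3                score 4/16    identity 34.9
  chembl:CHEMBL_thy      score -       identity 100.0
  chebi:CHEBI_ade        score -       identity 100.0
cluster 2 (best PDB score None):
  chebi:CHEBI_so4        score -       identity 100.0
```

Reading it: the self-complex's ligand achieves its ceiling (16/16 = 3·4
hydrogen bonds + 2·2 contacts, all to identical residues); the 90% homolog
keeps a conserved binding site and also reaches 16; at 60% the site is
merely similar (2·4 + 1·2 = 10) and at 30% dissimilar (1·4 + 0·2 = 4) — the
score tracks binding-site conservation while the geometry is identical.
Source-only compounds carry no structural score and follow, ordered by
associated-protein identity; the sulfate ends up in its own cluster because
it shares no subgraph with the pyrimidinone family. Comparing against the
study's cognate molecule,

```python
ev = evaluate_against_cognates(result, study.cognates)
```

reports a best similarity of 1.00 (the cognate itself is recovered from the
library, as `pdb:LG0`) with 6 co-clustered molecules.

## Command line

```
ligsearch fixtures --seed 2 --out study/               # emit a synthetic study
ligsearch run --query study/query.fasta --library study/library \
    --annotations study/annotations.tsv --sources study/compounds.tsv \
    --out results.tsv
ligsearch evaluate --result results.tsv --cognates cognates.tsv \
    --molecules molecules.tsv
```

`run` writes one TSV row per candidate (cluster rank and id, ligand id,
source, achieved/maximum score, structure and chain, associated identity,
cross-references, molecular weight, heavy atoms) and exits 4 — distinct from
failure — when the search completes but finds nothing.

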