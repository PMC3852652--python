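import numpy as np
import pytest

from oracles import sw_score_bruteforce

from ligsearch.align import (AlignError, build_query_anchored_msa,
                             build_sequence_db, load_matrix, rank_hits,
                             smith_waterman)
from ligsearch.domain_partition import DomainAnnotation
from ligsearch.fixtures import make_homolog
from ligsearch.formats_io import Structure, Residue, Atom

AA = "ACDEFGHIKLMNPQRSTVWY"


def _chain_structure(sid, seq):
    residues = [Residue(chain_id="A", seq_num=i + 1, insertion_code="",
                        res_type="ALA", atoms=[])
                for i in range(len(seq))]
    return Structure(id=sid, chains={"A": residues}, seqres={"A": seq})


class TestSmithWaterman:
    def test_self_alignment_is_full_identity(self):
        pair = smith_waterman("MKVLLA", "MKVLLA")
        assert pair.identity_pct == 100.0
        assert pair.matched_columns == [(i, i) for i in range(1, 7)]

    def test_no_positive_scoring_pair(self):
        pair = smith_waterman("AAAA", "CCCC")
        assert pair.score == 0.0
        assert pair.aligned_columns == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignError):
            smith_waterman("", "MKV")

    def test_score_matches_bruteforce_dp(self):
        """Affine-gap engine equals the explicit gap-length enumeration DP."""
        rng = np.random.default_rng(42)
        matrix = load_matrix("BLOSUM62")
        for _ in range(30):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            pair = smith_waterman(a, b)
            expected = sw_score_bruteforce(a, b, matrix, 11.0, 1.0)
            assert pair.score == pytest.approx(expected), (a, b)

    def test_identity_excludes_gap_columns(self):
        # one deletion inside an otherwise identical region
        a = "MKVDEFGHIKLW"
        b = "MKVDEGHIKLW"   # F removed
        pair = smith_waterman(a, b)
        assert pair.identity_pct == 100.0
        assert any(q is not None and h is None for q, h in pair.aligned_columns)


class TestRankHits:
    def test_self_hit_ranks_first(self):
        db = [("other", "WYWYWYWYWY"), ("self", "MKVLLAGKVMKVLLA")]
        hits = rank_hits("MKVLLAGKVMKVLLA", db, n=20)
        assert hits[0].hit_id == "self"
        assert hits[0].identity_pct == 100.0

    def test_n_larger_than_db_returns_all(self):
        db = [("a", "MKVLLA"), ("b", "MKVLLG")]
        assert len(rank_hits("MKVLLA", db, n=20)) == 2

    def test_planted_identity_gradient_orders_hits(self):
        rng = np.random.default_rng(3)
        query = "".join(rng.choice(list(AA), size=120))
        db = [(f"id{t}", make_homolog(query, t, seed=t)) for t in (90, 60, 30)]
        hits = rank_hits(query, db, n=20)
        assert [h.hit_id for h in hits] == ["id90", "id60", "id30"]

    def test_reranking_is_deterministic(self):
        db = [("a", "MKVLLAGKV"), ("b", "MKVLLAGKV"), ("c", "MKVLAGKV")]
        first = rank_hits("MKVLLAGKV", db)
        second = rank_hits("MKVLLAGKV", db)
        assert [(h.hit_id, h.score) for h in first] == \
               [(h.hit_id, h.score) for h in second]
        assert [h.hit_id for h in first][:2] == ["a", "b"]   # tie by entry id


class TestSequenceDb:
    def test_split_domain_entry_concatenates_segments(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), size=340))
        st = _chain_structure("1got", seq)
        anns = [
            DomainAnnotation("1got_A", "d1", segments=[(6, 57), (177, 331)]),
            DomainAnnotation("1got_A", "d2", segments=[(58, 176)]),
        ]
        entries = build_sequence_db([st], anns)
        kinds = [(e.entry_id, e.kind) for e in entries]
        assert ("1got_A", "full_chain") in kinds
        split = next(e for e in entries if e.entry_id == "1got_A_d1")
        assert len(split.sequence) == 52 + 155 == 207
        assert split.sequence == seq[5:57] + seq[176:331]
        # split-domain coordinate mapping crosses the segment boundary
        assert split.entry_pos_to_chain_pos(52) == 57
        assert split.entry_pos_to_chain_pos(53) == 177

    def test_no_annotations_gives_full_chain_only(self):
        st = _chain_structure("s1", "MKVLLAGKVW")
        entries = build_sequence_db([st])
        assert [e.kind for e in entries] == ["full_chain"]

    def test_unknown_chain_annotation_skipped(self, caplog):
        st = _chain_structure("s1", "MKVLLAGKVW")
        ann = DomainAnnotation("s2_B", "dX", segments=[(1, 5)])
        with caplog.at_level("WARNING"):
            entries = build_sequence_db([st], [ann])
        assert len(entries) == 1
        assert "unknown chain" in caplog.text

    def test_domain_lengths_bounded_by_chain(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(AA), size=200))
        st = _chain_structure("s1", seq)
        anns = [DomainAnnotation("s1_A", "d1", segments=[(1, 80)]),
                DomainAnnotation("s1_A", "d2", segments=[(81, 200)])]
        entries = build_sequence_db([st], anns)
        domain_total = sum(len(e.sequence) for e in entries if e.kind == "domain")
        assert domain_total <= len(seq)


class TestQueryAnchoredMsa:
    def test_single_pair_row_equals_pairwise_mapping(self):
        pair = smith_waterman("MKVLLAGKV", "MKVLLAGKV", hit_id="h1")
        msa = build_query_anchored_msa([pair])
        assert msa.rows["h1"] == pair.query_to_hit()

    def test_identical_hits_have_identical_rows(self):
        p1 = smith_waterman("MKVLLAGKV", "MKVLAGKV", hit_id="h1")
        p2 = smith_waterman("MKVLLAGKV", "MKVLAGKV", hit_id="h2")
        msa = build_query_anchored_msa([p1, p2])
        assert msa.rows["h1"] == msa.rows["h2"]

    def test_mixed_query_ids_rejected(self):
        p1 = smith_waterman("MKVLLA", "MKVLLA", query_id="q1", hit_id="h1")
        p2 = smith_waterman("MKVLLA", "MKVLLA", query_id="q2", hit_id="h2")
        with pytest.raises(AlignError):
            build_query_anchored_msa([p1, p2])

    def test_homolog_equivalences_match_planted_correspondence(self):
        """Substitution-only homologs keep the ungapped position correspondence."""
        rng = np.random.default_rng(9)
        query = "".join(rng.choice(list(AA), size=150))
        pairs = [smith_waterman(query, make_homolog(query, t, seed=t),
                                hit_id=f"h{t}") for t in (90, 80, 70)]
        msa = build_query_anchored_msa(pairs)
        eqs = msa.equivalences("h90", "h80")
        agree = sum(1 for x, y in eqs if x == y)
        assert agree / len(eqs) >= 0.95
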