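import numpy as np
import pytest

from ligsearch.align import AlignmentPair, smith_waterman
from ligsearch.domain_partition import (DomainAnnotation, DomainPartition,
                                        map_domain_to_query, partition_query,
                                        read_annotations_tsv)


def _identity_pair(length, hit_id="h1", score=500.0, skip_hit=()):
    """Alignment covering 1..length; ``skip_hit`` positions are deleted in the hit."""
    columns = []
    h = 0
    for q in range(1, length + 1):
        h += 1
        while h in skip_hit:
            columns.append((None, h))
            h += 1
        columns.append((q, h))
    return AlignmentPair(query_id="q", hit_id=hit_id, score=score,
                         aligned_columns=columns, identity_pct=100.0)


def _offset_pair(q_start, h_start, length, hit_id="h1", score=100.0):
    columns = [(q_start + i, h_start + i) for i in range(length)]
    return AlignmentPair(query_id="q", hit_id=hit_id, score=score,
                         aligned_columns=columns, identity_pct=100.0)


def _segments(partition):
    return {d.label: d.segments for d in partition.assigned}


class TestMapDomainToQuery:
    def test_identity_mapping(self):
        pair = _identity_pair(100)
        ann = DomainAnnotation("h1", "d1", segments=[(10, 50)])
        assert map_domain_to_query(ann, pair) == [(10, 50)]

    def test_domain_outside_aligned_region_maps_to_nothing(self):
        pair = _offset_pair(q_start=1, h_start=1, length=40)
        ann = DomainAnnotation("h1", "d1", segments=[(200, 300)])
        assert map_domain_to_query(ann, pair) is None

    def test_deletion_inside_domain_shortens_interval(self):
        # hit positions 20..24 are unaligned (deleted from the query side)
        pair = smith_waterman("A" * 0 + "MKVDEFGHIKLWMKVDEFGHIKLWMKVDEFGHIKLW",
                              "MKVDEFGHIKLWMKVDEFGHIKLWMKVDEFGHIKLW")
        ann = DomainAnnotation("hit", "d1", segments=[(1, 36)])
        full = map_domain_to_query(ann, pair)
        assert full == [(1, 36)]
        # build a synthetic pair with a 5-residue gap in the query coverage
        columns = ([(q, q) for q in range(1, 16)]
                   + [(None, h) for h in range(16, 21)]
                   + [(q - 5, q) for q in range(21, 46)])
        gapped = AlignmentPair("q", "hit", 100.0, columns, 100.0)
        ann2 = DomainAnnotation("hit", "d1", segments=[(1, 45)])
        (interval,) = map_domain_to_query(ann2, gapped)
        assert interval == (1, 40)   # 5 residues shorter than the domain

    def test_small_fragments_dropped(self):
        pair = _identity_pair(100)
        ann = DomainAnnotation("h1", "d1", segments=[(10, 20)])   # 11 residues
        assert map_domain_to_query(ann, pair, min_mapped=20) is None


class TestPartitionQuery:
    def test_no_annotations_long_query_is_unknown_domain(self):
        part = partition_query(150, [])
        assert len(part.assigned) == 1
        dom = part.assigned[0]
        assert dom.kind == "unknown" and dom.segments == [(1, 150)]

    def test_linker_split_at_midpoint(self):
        pair = _identity_pair(250, score=900.0)
        anns = [DomainAnnotation("h1", "d1", segments=[(1, 100)]),
                DomainAnnotation("h1", "d2", segments=[(151, 250)])]
        part = partition_query(250, [(pair, anns)])
        assert _segments(part) == {"d1": [(1, 125)], "d2": [(126, 250)]}

    def test_odd_linker_extra_residue_goes_n_terminal(self):
        pair = _identity_pair(250, score=900.0)
        anns = [DomainAnnotation("h1", "d1", segments=[(1, 100)]),
                DomainAnnotation("h1", "d2", segments=[(152, 250)])]
        part = partition_query(250, [(pair, anns)])
        assert _segments(part) == {"d1": [(1, 126)], "d2": [(127, 250)]}

    def test_overlapping_candidate_rejected(self):
        best = _identity_pair(250, hit_id="h1", score=900.0)
        worse = _identity_pair(250, hit_id="h2", score=500.0)
        anns1 = [DomainAnnotation("h1", "d1", segments=[(1, 100)])]
        anns2 = [DomainAnnotation("h2", "dX", segments=[(90, 180)])]
        part = partition_query(250, [(best, anns1), (worse, anns2)])
        labels = [d.label for d in part.assigned]
        assert "d1" in labels and "dX" not in labels
        # 101-180 later resolved by the unknown/linker/terminal rules
        assert part.query_len == 250

    def test_unassigned_run_over_threshold_becomes_unknown(self):
        pair = _identity_pair(400, score=900.0)
        anns = [DomainAnnotation("h1", "d1", segments=[(1, 100)])]
        part = partition_query(400, [(pair, anns)])
        unknown = [d for d in part.assigned if d.kind == "unknown"]
        assert len(unknown) == 1
        assert unknown[0].segments == [(101, 400)]

    def test_terminal_run_below_threshold_merges_into_neighbour(self):
        pair = _identity_pair(150, score=900.0)
        anns = [DomainAnnotation("h1", "d1", segments=[(31, 120)])]
        part = partition_query(150, [(pair, anns)])
        assert _segments(part) == {"d1": [(1, 150)]}

    def test_identical_homolog_recovers_planted_domains(self):
        pair = _identity_pair(250, score=900.0)
        anns = [DomainAnnotation("h1", "d1", segments=[(1, 110)]),
                DomainAnnotation("h1", "d2", segments=[(111, 250)])]
        part = partition_query(250, [(pair, anns)])
        assert _segments(part) == {"d1": [(1, 110)], "d2": [(111, 250)]}

    def test_query_len_must_be_positive(self):
        with pytest.raises(ValueError):
            partition_query(0, [])

    @pytest.mark.parametrize("n_scenarios", [80])
    def test_random_scenarios_always_partition_exactly(self, n_scenarios):
        """Disjoint segments covering [1, L] for arbitrary annotation soups."""
        rng = np.random.default_rng(11)
        for _ in range(n_scenarios):
            length = int(rng.integers(30, 600))
            ranked = []
            for h in range(rng.integers(0, 5)):
                cov_start = int(rng.integers(1, max(2, length // 2)))
                cov_len = int(rng.integers(10, length))
                pair = _offset_pair(cov_start, 1,
                                    min(cov_len, length - cov_start + 1),
                                    hit_id=f"h{h}",
                                    score=float(rng.integers(50, 500)))
                anns = []
                for d in range(rng.integers(0, 4)):
                    s = int(rng.integers(1, length))
                    e = min(length, s + int(rng.integers(5, 200)))
                    anns.append(DomainAnnotation(f"h{h}", f"h{h}d{d}",
                                                 segments=[(s, e)]))
                ranked.append((pair, anns))
            part = partition_query(length, ranked)   # validates in __post_init__
            assert isinstance(part, DomainPartition)

    def test_equal_scores_tie_broken_by_hit_id(self):
        anns_a = [DomainAnnotation("ha", "da", segments=[(1, 120)])]
        anns_b = [DomainAnnotation("hb", "db", segments=[(1, 120)])]
        ranked = [(_identity_pair(150, hit_id="hb", score=100.0), anns_b),
                  (_identity_pair(150, hit_id="ha", score=100.0), anns_a)]
        part = partition_query(150, ranked)
        assert part.assigned[0].label == "da"       # 'ha' < 'hb'


def test_read_annotations_tsv_parses_split_segments():
    text = ("structure_id\tchain_id\tdomain_id\tsegments\tkind\n"
            "1got\tA\td1\t6-57,177-331\tcath_like\n"
            "1got\tA\td2\t58-176\tpfam_like\n")
    anns = read_annotations_tsv(text)
    assert anns[0].source_seq_id == "1got_A"
    assert anns[0].segments == [(6, 57), (177, 331)]
    assert anns[1].kind == "pfam_like"
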