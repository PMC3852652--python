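"""Local sequence alignment, hit ranking and the split-domain sequence database.

Homology search is modelled by a single Smith–Waterman engine (Biopython's
``PairwiseAligner`` in local mode) with BLOSUM62 and affine gaps: a gap of
length *k* costs ``gap_open + k * gap_extend`` (defaults 11 and 1).  The
sequence database holds the full-length chain of every library structure
plus one entry per annotated domain, so 'split' domains — domains whose
residues occupy two or more non-contiguous segments — can still be matched
by their concatenated sequence.  A query-anchored multiple alignment stacks
the pairwise alignments: two hit residues are equivalent iff they align to
the same query position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


class AlignError(ValueError):
    pass


@lru_cache(maxsize=8)
def load_matrix(name: str = DEFAULT_MATRIX):
    """Load a substitution matrix by its NCBI name (e.g. BLOSUM62, PAM250)."""
    return substitution_matrices.load(name)


@dataclass
class AlignmentPair:
    """An optimal local alignment between the query and one hit.

    ``aligned_columns`` lists ``(query_pos, hit_pos)`` pairs in 1-based
    coordinates; a ``None`` on either side marks a gap column.
    ``identity_pct`` is 100 x identical columns / aligned (non-gap) columns.
    """

    query_id: str
    hit_id: str
    score: float
    aligned_columns: List[Tuple[Optional[int], Optional[int]]]
    identity_pct: float

    @property
    def matched_columns(self) -> List[Tuple[int, int]]:
        return [(q, h) for q, h in self.aligned_columns if q is not None and h is not None]

    def query_to_hit(self) -> Dict[int, int]:
        return {q: h for q, h in self.matched_columns}

    def hit_to_query(self) -> Dict[int, int]:
        return {h: q for q, h in self.matched_columns}


@dataclass
class SequenceDbEntry:
    """One searchable sequence: a full chain or one (possibly split) domain."""

    entry_id: str
    parent_structure_id: str
    chain_id: str
    kind: str                      # 'full_chain' | 'domain'
    segments: List[Tuple[int, int]]  # 1-based inclusive, in chain-sequence coords
    sequence: str

    def __post_init__(self):
        if self.kind not in ("full_chain", "domain"):
            raise ValueError(f"bad entry kind {self.kind!r}")
        total = sum(e - s + 1 for s, e in self.segments)
        if total != len(self.sequence):
            raise ValueError(
                f"{self.entry_id}: segment length {total} != sequence length "
                f"{len(self.sequence)}")

    def entry_pos_to_chain_pos(self, pos: int) -> int:
        """Map a 1-based position in the entry sequence to a chain position."""
        off = 0
        for s, e in self.segments:
            seg_len = e - s + 1
            if pos <= off + seg_len:
                return s + (pos - off - 1)
            off += seg_len
        raise IndexError(f"position {pos} outside entry {self.entry_id}")


@dataclass
class MultipleAlignment:
    """Query-anchored stacking of pairwise alignments."""

    query_id: str
    rows: Dict[str, Dict[int, int]]   # hit_id -> {query_pos: hit_pos}

    def equivalences(self, hit_a: str, hit_b: str) -> List[Tuple[int, int]]:
        """Residue pairs of two hits aligned to the same query position."""
        row_a, row_b = self.rows[hit_a], self.rows[hit_b]
        return sorted((row_a[q], row_b[q]) for q in row_a.keys() & row_b.keys())


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise AlignError("gap penalties must be positive")
    if isinstance(matrix, str) or matrix is None:
        matrix = load_matrix(matrix or DEFAULT_MATRIX)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gapped position, so a
    # length-k gap costs gap_open + k*gap_extend under this parametrisation.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(a: str, b: str, matrix=None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   query_id: str = "query", hit_id: str = "hit") -> AlignmentPair:
    """Optimal local alignment of ``a`` (query) vs ``b`` (hit), affine gaps."""
    if not a or not b:
        raise AlignError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    result = aligner.align(a, b)
    score = float(result.score)
    if score <= 0:
        return AlignmentPair(query_id=query_id, hit_id=hit_id, score=0.0,
                             aligned_columns=[], identity_pct=0.0)
    aln = result[0]
    columns: List[Tuple[Optional[int], Optional[int]]] = []
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = None
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            for q in range(prev_a_end, a_start):     # deletion in hit
                columns.append((q + 1, None))
            for h in range(prev_b_end, b_start):     # insertion in hit
                columns.append((None, h + 1))
        for q, h in zip(range(a_start, a_end), range(b_start, b_end)):
            columns.append((q + 1, h + 1))
        prev_a_end, prev_b_end = a_end, b_end
    matched = [(q, h) for q, h in columns if q is not None and h is not None]
    identical = sum(1 for q, h in matched if a[q - 1] == b[h - 1])
    identity = 100.0 * identical / len(matched) if matched else 0.0
    return AlignmentPair(query_id=query_id, hit_id=hit_id, score=score,
                         aligned_columns=columns,
                         identity_pct=round(identity, 1))


def rank_hits(query: str, db: Iterable, n: int = 20, matrix=None,
              gap_open: float = DEFAULT_GAP_OPEN,
              gap_extend: float = DEFAULT_GAP_EXTEND,
              query_id: str = "query") -> List[AlignmentPair]:
    """Align the query against every database entry and keep the top ``n``.

    ``db`` entries are :class:`SequenceDbEntry` objects or ``(id, sequence)``
    pairs.  Hits sort by score descending, ties by entry id ascending;
    zero-score (empty) alignments are dropped.
    """
    if n < 1:
        raise AlignError("n must be >= 1")
    pairs = []
    for entry in db:
        if isinstance(entry, SequenceDbEntry):
            eid, seq = entry.entry_id, entry.sequence
        else:
            eid, seq = entry
        if not seq:
            continue
        pair = smith_waterman(query, seq, matrix=matrix, gap_open=gap_open,
                              gap_extend=gap_extend, query_id=query_id, hit_id=eid)
        if pair.score > 0:
            pairs.append(pair)
    pairs.sort(key=lambda p: (-p.score, p.hit_id))
    return pairs[:n]


def build_sequence_db(structures: Iterable, annotations: Iterable = ()) -> List[SequenceDbEntry]:
    """Full-chain plus per-domain sequence entries for a structure library.

    Annotations carry ``source_seq_id`` (``<structure_id>_<chain_id>``),
    ``domain_id`` and 1-based inclusive ``segments`` in chain-sequence
    coordinates; split domains yield a single entry whose sequence
    concatenates the segments in order.  Annotations referencing unknown
    chains are skipped with a warning.
    """
    entries: List[SequenceDbEntry] = []
    chain_seqs: Dict[str, Tuple[str, str, str]] = {}
    for st in structures:
        for chain_id in st.chains:
            seq = st.chain_sequence(chain_id)
            if not seq:
                continue
            eid = f"{st.id}_{chain_id}"
            chain_seqs[eid] = (st.id, chain_id, seq)
            entries.append(SequenceDbEntry(
                entry_id=eid, parent_structure_id=st.id, chain_id=chain_id,
                kind="full_chain", segments=[(1, len(seq))], sequence=seq))
    for ann in annotations:
        parent = chain_seqs.get(ann.source_seq_id)
        if parent is None:
            logger.warning("annotation %s references unknown chain %s; skipped",
                           ann.domain_id, ann.source_seq_id)
            continue
        sid, chain_id, seq = parent
        if any(e > len(seq) or s < 1 for s, e in ann.segments):
            logger.warning("annotation %s segments outside chain %s; skipped",
                           ann.domain_id, ann.source_seq_id)
            continue
        subseq = "".join(seq[s - 1:e] for s, e in ann.segments)
        entries.append(SequenceDbEntry(
            entry_id=f"{ann.source_seq_id}_{ann.domain_id}",
            parent_structure_id=sid, chain_id=chain_id, kind="domain",
            segments=list(ann.segments), sequence=subseq))
    return entries


def build_query_anchored_msa(pairs: Sequence[AlignmentPair]) -> MultipleAlignment:
    """Derive a query-anchored multiple alignment from pairwise alignments."""
    if not pairs:
        raise AlignError("at least one pairwise alignment required")
    query_ids = {p.query_id for p in pairs}
    if len(query_ids) != 1:
        raise AlignError(f"pairwise alignments have mixed query ids: {sorted(query_ids)}")
    rows = {p.hit_id: p.query_to_hit() for p in pairs}
    return MultipleAlignment(query_id=pairs[0].query_id, rows=rows)
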