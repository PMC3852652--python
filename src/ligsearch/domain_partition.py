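"""Partition a query sequence into predicted domains from homolog annotations.

Domain annotations of ranked homologs are transferred onto the query through
the pairwise alignments and accepted greedily, best hit first, with a strict
no-overlap rule.  Afterwards any unassigned run longer than 100 residues
becomes a domain of unknown type; each remaining internal run (a linker) is
split at its midpoint between the flanking domains, and terminal runs are
merged into the single adjacent domain.  The result is always an exact
partition of [1, query length].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .align import AlignmentPair

logger = logging.getLogger(__name__)

DEFAULT_UNKNOWN_MIN = 100   # residues: longer unassigned runs become domains
DEFAULT_MIN_MAPPED = 20     # residues: smaller mapped fragments are noise

DOMAIN_KINDS = ("cath_like", "pfam_like", "unknown")


@dataclass
class DomainAnnotation:
    """A structural (CATH-like) or sequence (Pfam-like) domain of a library chain."""

    source_seq_id: str
    domain_id: str
    segments: List[Tuple[int, int]]   # 1-based inclusive, source-sequence coords
    kind: str = "cath_like"

    def __post_init__(self):
        if self.kind not in ("cath_like", "pfam_like"):
            raise ValueError(f"bad annotation kind {self.kind!r}")
        segs = sorted((int(s), int(e)) for s, e in self.segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping segments in domain {self.domain_id}")
        if any(s > e or s < 1 for s, e in segs):
            raise ValueError(f"invalid segment in domain {self.domain_id}")
        self.segments = segs


@dataclass
class AssignedDomain:
    label: str
    kind: str                          # cath_like | pfam_like | unknown
    segments: List[Tuple[int, int]]    # 1-based inclusive query intervals
    provenance: Optional[str] = None   # hit id the domain was transferred from


@dataclass
class DomainPartition:
    query_len: int
    assigned: List[AssignedDomain]

    def __post_init__(self):
        covered = []
        for dom in self.assigned:
            covered.extend(range(s, e + 1) for s, e in dom.segments)
        flat = sorted(p for rng in covered for p in rng)
        if flat != list(range(1, self.query_len + 1)):
            raise ValueError("assigned domains do not exactly partition the query")

    def domain_of(self, pos: int) -> AssignedDomain:
        for dom in self.assigned:
            if any(s <= pos <= e for s, e in dom.segments):
                return dom
        raise IndexError(pos)


def read_annotations_tsv(text: str) -> List[DomainAnnotation]:
    """Read a domain-annotation table.

    Columns: ``structure_id, chain_id, domain_id, segments`` with segments
    written ``"6-57,177-331"``; an optional ``kind`` column defaults to
    ``cath_like``.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        segments = []
        for part in row["segments"].split(","):
            s, e = part.strip().split("-")
            segments.append((int(s), int(e)))
        out.append(DomainAnnotation(
            source_seq_id=f"{row['structure_id']}_{row['chain_id']}",
            domain_id=row["domain_id"], segments=segments,
            kind=row.get("kind", "") or "cath_like"))
    return out


def map_domain_to_query(annotation: DomainAnnotation, pair: AlignmentPair,
                        min_mapped: int = DEFAULT_MIN_MAPPED
                        ) -> Optional[List[Tuple[int, int]]]:
    """Transfer a hit domain onto the query through the pairwise alignment.

    Each annotation segment maps to the minimal query interval covering all
    query positions aligned to it; segments with fewer than ``min_mapped``
    mapped residues are dropped as alignment noise.  Returns ``None`` when
    every segment drops (e.g. the domain lies outside the aligned region).
    """
    hit_to_query = pair.hit_to_query()
    intervals = []
    for s, e in annotation.segments:
        qpos = [hit_to_query[h] for h in range(s, e + 1) if h in hit_to_query]
        if len(qpos) < min_mapped:
            continue
        intervals.append((min(qpos), max(qpos)))
    return intervals or None


def _runs(free: List[bool], length: int) -> List[Tuple[int, int]]:
    runs, start = [], None
    for pos in range(1, length + 1):
        if free[pos] and start is None:
            start = pos
        elif not free[pos] and start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, length))
    return runs


def partition_query(query_len: int,
                    ranked: Sequence[Tuple[AlignmentPair, Sequence[DomainAnnotation]]],
                    unknown_min: int = DEFAULT_UNKNOWN_MIN,
                    min_mapped: int = DEFAULT_MIN_MAPPED) -> DomainPartition:
    """Greedy domain assignment in hit-rank order, then closure to a partition.

    ``ranked`` pairs each hit's alignment with that hit's annotations, ordered
    by hit score descending (ties are re-broken deterministically by hit id).
    A candidate domain is accepted only if none of its mapped query intervals
    overlaps a previously assigned domain.
    """
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    order = sorted(range(len(ranked)),
                   key=lambda k: (-ranked[k][0].score, ranked[k][0].hit_id))
    free = [True] * (query_len + 2)
    owner: List[Optional[int]] = [None] * (query_len + 2)
    domains: List[AssignedDomain] = []

    for k in order:
        pair, annotations = ranked[k]
        for ann in sorted(annotations, key=lambda a: a.domain_id):
            intervals = map_domain_to_query(ann, pair, min_mapped=min_mapped)
            if intervals is None:
                continue
            # clamp to the query range and merge any mutually overlapping
            # intervals so one domain never claims a position twice
            clamped = sorted((max(1, s), min(e, query_len))
                             for s, e in intervals if s <= query_len and e >= 1)
            if not clamped:
                continue
            merged_iv = [list(clamped[0])]
            for s, e in clamped[1:]:
                if s <= merged_iv[-1][1] + 1:
                    merged_iv[-1][1] = max(merged_iv[-1][1], e)
                else:
                    merged_iv.append([s, e])
            intervals = [(s, e) for s, e in merged_iv]
            positions = [p for s, e in intervals for p in range(s, e + 1)]
            if not all(free[p] for p in positions):
                continue
            idx = len(domains)
            domains.append(AssignedDomain(label=ann.domain_id, kind=ann.kind,
                                          segments=list(intervals),
                                          provenance=pair.hit_id))
            for p in positions:
                free[p] = False
                owner[p] = idx

    # unassigned runs longer than the threshold become unknown-type domains
    unknown_count = 0
    for s, e in _runs(free, query_len):
        if e - s + 1 > unknown_min:
            unknown_count += 1
            idx = len(domains)
            domains.append(AssignedDomain(label=f"unknown_{unknown_count}",
                                          kind="unknown", segments=[(s, e)]))
            for p in range(s, e + 1):
                free[p] = False
                owner[p] = idx

    if not domains:
        # degenerate short query with nothing assigned: one unknown domain
        return DomainPartition(query_len=query_len, assigned=[
            AssignedDomain(label="unknown_1", kind="unknown",
                           segments=[(1, query_len)])])

    # linkers: internal runs split at their midpoint (extra residue to the
    # N-terminal side); terminal runs merge into the single adjacent domain
    extra: Dict[int, List[Tuple[int, int]]] = {}
    for s, e in _runs(free, query_len):
        left = owner[s - 1] if s > 1 else None
        right = owner[e + 1] if e < query_len else None
        if left is not None and right is not None:
            mid = s + (e - s + 1 + 1) // 2 - 1   # N-side gets the odd residue
            extra.setdefault(left, []).append((s, mid))
            if mid + 1 <= e:
                extra.setdefault(right, []).append((mid + 1, e))
        elif left is not None:
            extra.setdefault(left, []).append((s, e))
        elif right is not None:
            extra.setdefault(right, []).append((s, e))

    assigned = []
    for idx, dom in enumerate(domains):
        segs = sorted(dom.segments + extra.get(idx, []))
        merged = [list(segs[0])]
        for s, e in segs[1:]:
            if s == merged[-1][1] + 1:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        assigned.append(AssignedDomain(label=dom.label, kind=dom.kind,
                                       segments=[(s, e) for s, e in merged],
                                       provenance=dom.provenance))
    return DomainPartition(query_len=query_len, assigned=assigned)
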