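"""Four-phase contig integration.

Given contig sets from several de novo assemblers run on the same
bacterial genome, produce one hybrid contig set of higher contiguity:

1. **Representative selection and extension** — the largest contig of
   the remaining pool anchors each round; pool contigs whose major
   portion (> ``contain_rate`` of their length at > ``contain_identity``)
   lies within the representative are removed, and contigs aligned to
   the representative's ends with more than ``extend_rate`` of their
   length extend it.
2. **Misassembly screening** — a representative found in the middle of
   two individual contigs of a single assembly is treated as misjoined
   and replaced by those two contigs; internal representative regions
   that no other input contig covers are clipped out and the
   representative is split around them.
3. **Iterative overlap merging** — contigs with a proper end-to-end
   overlap longer than ``merge_frac`` of the smaller contig are merged,
   longest overlap first, re-aligning after every merge so that one
   contig can bridge two others.  Alongside, the maximal size R of
   repetitive regions is estimated from contig intervals aligned to at
   least two different regions.
4. **Repeat-aware final merging** — remaining end-to-end overlaps are
   merged only when longer than R, which prevents joining two contigs
   whose only shared sequence is a repeat copy.

All thresholds are strict ``>`` comparisons.  The procedure is
deterministic: no randomness anywhere, all ties broken by contig ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .align import (
    AlignConfig,
    AlignmentCache,
    AlignmentRecord,
    AlignmentTable,
    align_sets,
    alignment_rate,
    interval_union_length,
)
from .formats import Contig, revcomp

logger = logging.getLogger("asmblend")

__all__ = [
    "IntegrationConfig",
    "IntegrationResult",
    "RepeatEstimate",
    "RepresentativeSet",
    "OverlapCandidate",
    "WorkingContig",
    "Segment",
    "pick_representative",
    "phase1_collapse",
    "extend_representative",
    "detect_misjoin",
    "phase2_screen",
    "find_end_overlap",
    "phase3_iterative_merge",
    "phase4_merge",
    "integrate",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Every threshold of the integration procedure.

    Fractions are strict lower bounds (a value exactly at the threshold
    is rejected).  ``end_window`` defines how close to a contig
    extremity an aligned block must reach to count as end-anchored, and
    doubles as the breakpoint tolerance in misassembly screening.
    """

    contain_rate: float = 0.95
    contain_identity: float = 0.95
    extend_rate: float = 0.80
    extend_identity: float = 0.95
    merge_frac: float = 0.30
    min_contig_len: int = 100
    end_window: int = 100
    min_repeat_evidence_len: int = 50
    align: AlignConfig = field(default_factory=AlignConfig)

    def __post_init__(self) -> None:
        for name in ("contain_rate", "contain_identity", "extend_rate",
                     "extend_identity", "merge_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_contig_len < 1:
            raise ValueError("min_contig_len must be >= 1")


# ---------------------------------------------------------------------------
# Provenance-tracking working contigs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A run of output bases copied verbatim from one input contig.

    ``start:end`` is the half-open interval on the *input* contig;
    ``strand`` records whether the copy is reverse-complemented.
    """

    source: str
    name: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WorkingContig:
    """A contig under construction plus its base-level provenance.

    The segment list is a partition of the sequence: segment lengths sum
    to the sequence length, in order.
    """

    id: str
    seq: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if sum(len(s) for s in self.segments) != len(self.seq):
            raise ValueError(f"provenance of {self.id!r} does not partition its sequence")

    @classmethod
    def from_contig(cls, contig: Contig, wid: str | None = None) -> "WorkingContig":
        seg = Segment(contig.source, contig.id, 0, contig.length)
        return cls(id=wid or contig.id, seq=contig.seq, segments=(seg,))

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def source(self) -> str:
        return self.segments[0].source

    @property
    def provenance_keys(self) -> set[tuple[str, str]]:
        return {(s.source, s.name) for s in self.segments}

    def reverse_complement(self) -> "WorkingContig":
        segs = tuple(
            Segment(s.source, s.name, s.start, s.end, "-" if s.strand == "+" else "+")
            for s in reversed(self.segments)
        )
        return WorkingContig(self.id, revcomp(self.seq), segs)

    def slice(self, i: int, j: int, wid: str | None = None) -> "WorkingContig":
        """Sub-contig over output interval [i, j), provenance cut to match."""
        if not 0 <= i < j <= len(self.seq):
            raise ValueError(f"bad slice [{i},{j}) of {self.id!r} (len {len(self.seq)})")
        segs: list[Segment] = []
        pos = 0
        for s in self.segments:
            s_lo, s_hi = pos, pos + len(s)
            lo, hi = max(i, s_lo), min(j, s_hi)
            if lo < hi:
                if s.strand == "+":
                    segs.append(Segment(s.source, s.name, s.start + (lo - s_lo),
                                        s.start + (hi - s_lo), "+"))
                else:
                    segs.append(Segment(s.source, s.name, s.end - (hi - s_lo),
                                        s.end - (lo - s_lo), "-"))
            pos = s_hi
        return WorkingContig(wid or self.id, self.seq[i:j], tuple(segs))

    @staticmethod
    def concat(wid: str, parts: Sequence["WorkingContig"]) -> "WorkingContig":
        seq = "".join(p.seq for p in parts)
        segs = tuple(s for p in parts for s in p.segments)
        return WorkingContig(wid, seq, segs)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class RepresentativeSet:
    """Ordered representative contigs plus per-contig provenance."""

    contigs: list[WorkingContig]

    @property
    def provenance(self) -> dict[str, list[tuple[str, str]]]:
        return {c.id: sorted(c.provenance_keys) for c in self.contigs}

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)


@dataclass(frozen=True)
class RepeatEstimate:
    """Maximum repetitive-region size R and its supporting intervals.

    ``supporting_intervals`` lists ``(contig_id, start, end)`` intervals
    aligned at high identity to at least two distinct, non-overlapping
    regions; ``max_repeat_len`` is the longest of them (0 when none).
    """

    max_repeat_len: int = 0
    supporting_intervals: tuple[tuple[str, int, int], ...] = ()


@dataclass(frozen=True)
class OverlapCandidate:
    """A proper end-to-end overlap joining two contigs."""

    left_id: str
    right_id: str
    record: AlignmentRecord
    orientation: str  # relative strand of right vs left
    overlap_len: int
    merged_len: int


@dataclass
class IntegrationResult:
    contigs: list[Contig]
    repeat: RepeatEstimate
    report: dict
    phase_outputs: dict[str, list[WorkingContig]]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _oriented(rec: AlignmentRecord, qlen: int) -> tuple[int, int]:
    """Query interval of ``rec`` in the frame where the query runs along
    the target's forward direction: (oq_start, oq_end)."""
    if rec.strand == "+":
        return rec.q_start, rec.q_end
    return qlen - rec.q_end, qlen - rec.q_start


def pick_representative(pool: Sequence) -> object:
    """Longest contig of the pool; ties go to the lexicographically
    smallest ``(source, id)``."""
    if not pool:
        raise ValueError("cannot pick a representative from an empty pool")
    return min(pool, key=lambda c: (-c.length, getattr(c, "source", ""), c.id))


def _containment_rate(
    table: AlignmentTable, query_id: str, target_id: str, min_identity: float
) -> float:
    recs = [
        r
        for r in table.for_pair(query_id, target_id)
        if r.identity > min_identity
    ]
    if not recs:
        return 0.0
    covered = interval_union_length((r.q_start, r.q_end) for r in recs)
    return covered / table.query_lengths[query_id]


def _remove_contained(
    contigs: list[WorkingContig], config: IntegrationConfig, cache: AlignmentCache
) -> list[WorkingContig]:
    """Drop every contig whose major portion lies within a longer one
    (non-redundancy sweep).  Shorter contigs are tested first against
    the current survivors."""
    ordered = sorted(contigs, key=lambda c: (c.length, c.source, c.id))
    survivors = list(contigs)
    for c in ordered:
        others = [o for o in survivors if o.id != c.id and o.length >= c.length]
        if not others:
            continue
        table = align_sets([c], others, config.align, cache)
        for o in others:
            if (
                _containment_rate(table, c.id, o.id, config.contain_identity)
                > config.contain_rate
            ):
                survivors = [s for s in survivors if s.id != c.id]
                break
    return survivors


# ---------------------------------------------------------------------------
# Phase 1 — representatives and extension
# ---------------------------------------------------------------------------


def extend_representative(
    rep: WorkingContig,
    pool: Sequence[WorkingContig],
    table: AlignmentTable,
    config: IntegrationConfig,
) -> WorkingContig:
    """One round of end extension: at most one extender per end.

    A pool contig qualifies for an end when a single alignment covering
    more than ``extend_rate`` of its length at identity above
    ``extend_identity`` reaches within ``end_window`` of that extremity
    and overhangs past it.  Demanding that the *extending* alignment
    itself carries the 80% keeps extension repeat-safe: a mostly
    contained contig cannot be attached by a short secondary block that
    merely echoes a repeat copy elsewhere.  Per end the longest overhang
    wins and its non-aligned part is appended (reverse-complemented as
    needed).
    """
    best: dict[str, tuple[int, tuple, WorkingContig, AlignmentRecord]] = {}
    rlen = rep.length
    for e in pool:
        if e.id == rep.id:
            continue
        recs = [
            r
            for r in table.for_pair(e.id, rep.id)
            if r.identity > config.extend_identity
            and r.q_span / e.length > config.extend_rate
        ]
        if not recs:
            continue
        for r in recs:
            oqs, oqe = _oriented(r, e.length)
            tiebreak = (e.source, e.id)

            def better(end: str, overhang: int) -> bool:
                cur = best.get(end)
                return cur is None or overhang > cur[0] or (
                    overhang == cur[0] and tiebreak < cur[1]
                )

            # right end of the representative
            if r.t_end >= rlen - config.end_window:
                overhang = (e.length - oqe) - (rlen - r.t_end)
                if overhang > 0 and better("right", overhang):
                    best["right"] = (overhang, tiebreak, e, r)
            # left end of the representative
            if r.t_start <= config.end_window:
                overhang = oqs - r.t_start
                if overhang > 0 and better("left", overhang):
                    best["left"] = (overhang, tiebreak, e, r)
    if not best:
        return rep
    parts: list[WorkingContig] = []
    if "left" in best:
        overhang, _, e, r = best["left"]
        oe = e.reverse_complement() if r.strand == "-" else e
        parts.append(oe.slice(0, overhang))
        logger.debug("extend %s left by %d bp from %s", rep.id, overhang, e.id)
    parts.append(rep)
    if "right" in best:
        overhang, _, e, r = best["right"]
        oe = e.reverse_complement() if r.strand == "-" else e
        parts.append(oe.slice(oe.length - overhang, oe.length))
        logger.debug("extend %s right by %d bp from %s", rep.id, overhang, e.id)
    return WorkingContig.concat(rep.id, parts)


def phase1_collapse(
    pool: Sequence[WorkingContig],
    config: IntegrationConfig,
    cache: AlignmentCache | None = None,
) -> RepresentativeSet:
    """Iterative representative selection, containment removal and end
    extension, until the pool is exhausted."""
    cache = cache or AlignmentCache()
    pool = list(pool)
    reps: list[WorkingContig] = []
    while pool:
        rep = pick_representative(pool)
        pool = [c for c in pool if c.id != rep.id]
        while True:
            if not pool:
                break
            table = align_sets(pool, [rep], config.align, cache)
            kept: list[WorkingContig] = []
            for c in pool:
                rate = _containment_rate(table, c.id, rep.id, config.contain_identity)
                if rate > config.contain_rate:
                    logger.debug("phase1: %s contained in %s (rate %.3f)", c.id, rep.id, rate)
                else:
                    kept.append(c)
            changed = len(kept) != len(pool)
            pool = kept
            if pool:
                table = align_sets(pool, [rep], config.align, cache)
                new_rep = extend_representative(rep, pool, table, config)
                if new_rep.length != rep.length:
                    rep = new_rep
                    changed = True
            if not changed:
                break
        reps.append(rep)
    return RepresentativeSet(contigs=reps)


# ---------------------------------------------------------------------------
# Phase 2 — misassembly screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MisjoinEvidence:
    breakpoint: int
    source: str
    left_contig: str
    right_contig: str


def detect_misjoin(
    rep: WorkingContig,
    inputs: Sequence[WorkingContig],
    table: AlignmentTable,
    config: IntegrationConfig,
    cache: AlignmentCache | None = None,
) -> list[MisjoinEvidence]:
    """Find internal breakpoints of ``rep`` contradicted by one assembly.

    Evidence: two distinct contigs of a single input assembly align at
    high identity to a prefix-side and a suffix-side region of the
    representative, the regions abut (within ``end_window``) at an
    internal position, both contigs continue past the junction on their
    own — and the two contigs do not themselves overlap end-to-end, so
    the junction is not corroborated anywhere.
    """
    cache = cache or AlignmentCache()
    w = config.end_window
    rlen = rep.length
    by_contig: dict[str, WorkingContig] = {c.id: c for c in inputs}
    by_source: dict[str, list[AlignmentRecord]] = {}
    for rec in table.records:
        if rec.target_id != rep.id or rec.identity < config.contain_identity:
            continue
        if rec.q_span < w or rec.t_span < w:
            continue
        src = by_contig[rec.query_id].source
        by_source.setdefault(src, []).append(rec)
    evidence: list[MisjoinEvidence] = []
    for src in sorted(by_source):
        recs = sorted(by_source[src], key=lambda r: (r.t_start, r.t_end, r.query_id))
        for i, r1 in enumerate(recs):
            for r2 in recs[i + 1 :]:
                if r1.query_id == r2.query_id:
                    continue
                gap = r2.t_start - r1.t_end
                if not -w <= gap <= w:
                    continue
                if r1.t_end <= w or r2.t_start >= rlen - w:
                    continue  # junction not internal
                e1 = by_contig[r1.query_id]
                e2 = by_contig[r2.query_id]
                o1s, o1e = _oriented(r1, e1.length)
                o2s, o2e = _oriented(r2, e2.length)
                if e1.length - o1e < w or o2s < w:
                    continue  # no divergence past the junction
                if _end_to_end_overlapping(e1, e2, r1, r2, config, cache):
                    continue  # genuine overlap corroborates the junction
                evidence.append(
                    MisjoinEvidence(
                        breakpoint=(r1.t_end + max(r1.t_end, r2.t_start)) // 2,
                        source=src,
                        left_contig=r1.query_id,
                        right_contig=r2.query_id,
                    )
                )
    evidence.sort(key=lambda ev: (ev.breakpoint, ev.source))
    return evidence


def _end_to_end_overlapping(
    e1: WorkingContig,
    e2: WorkingContig,
    r1: AlignmentRecord,
    r2: AlignmentRecord,
    config: IntegrationConfig,
    cache: AlignmentCache,
) -> bool:
    """Do e1 and e2 share a genuine overlap spanning the junction?

    ``r1``/``r2`` are the contigs' records against the representative;
    the contig positions adjacent to the junction are where each
    alignment stops.  If e1 and e2 align to each other across those
    positions, the junction is corroborated by real shared sequence.
    """
    w = config.end_window
    # position on e1 (forward coords) where its rep alignment ends
    junction_e1 = r1.q_end if r1.strand == "+" else r1.q_start
    junction_e2 = r2.q_start if r2.strand == "+" else r2.q_end
    table = align_sets([e1], [e2], config.align, cache)
    for rec in table.for_pair(e1.id, e2.id):
        if rec.identity < config.contain_identity:
            continue
        if min(rec.q_span, rec.t_span) < w:
            continue
        if (
            rec.q_start - w <= junction_e1 <= rec.q_end + w
            and rec.t_start - w <= junction_e2 <= rec.t_end + w
        ):
            return True
    return False


def phase2_screen(
    reps: RepresentativeSet,
    inputs: Sequence[WorkingContig],
    config: IntegrationConfig,
    cache: AlignmentCache | None = None,
) -> RepresentativeSet:
    """Remove misjoined representatives and clip uncertain regions.

    Misjoined representatives are replaced by the evidencing assembly's
    two contigs (supplemental representatives).  Any internal
    representative interval of at least ``end_window`` bases with zero
    coverage by input contigs outside the representative's own
    provenance is dropped and the representative split around it;
    terminal uncovered runs are clipped.  A final containment sweep
    restores non-redundancy.
    """
    cache = cache or AlignmentCache()
    w = config.end_window
    survivors: list[WorkingContig] = []
    supplemental: dict[str, WorkingContig] = {}
    by_id = {c.id: c for c in inputs}
    for rep in reps:
        table = align_sets(inputs, [rep], config.align, cache)
        evidence = detect_misjoin(rep, inputs, table, config, cache)
        if evidence:
            ev = evidence[0]
            logger.info(
                "phase2: %s misjoined at ~%d (evidence %s: %s | %s); replacing",
                rep.id, ev.breakpoint, ev.source, ev.left_contig, ev.right_contig,
            )
            for cid in (ev.left_contig, ev.right_contig):
                supplemental.setdefault(cid, by_id[cid])
            continue
        survivors.append(rep)
    for cid, c in sorted(supplemental.items()):
        if all(s.id != cid for s in survivors):
            survivors.append(c)

    screened: list[WorkingContig] = []
    for rep in survivors:
        table = align_sets(inputs, [rep], config.align, cache)
        by_contig = {c.id: c for c in inputs}
        cover: list[tuple[int, int, tuple[str, str]]] = [
            (
                r.t_start,
                r.t_end,
                (by_contig[r.query_id].source, by_contig[r.query_id].segments[0].name),
            )
            for r in table.records
            if r.target_id == rep.id and r.identity >= config.extend_identity
        ]
        pieces = _split_uncovered(rep, cover, config)
        if len(pieces) != 1 or pieces[0].length != rep.length:
            logger.info(
                "phase2: %s has uncertain regions; kept %d piece(s)",
                rep.id, len(pieces),
            )
        screened.extend(pieces)

    screened = [c for c in screened if c.length >= config.min_contig_len]
    screened = _remove_contained(screened, config, cache)
    return RepresentativeSet(contigs=screened)


def _split_uncovered(
    rep: WorkingContig,
    cover: list[tuple[int, int, tuple[str, str]]],
    config: IntegrationConfig,
) -> list[WorkingContig]:
    """Split/clip ``rep`` around uncertain runs of >= end_window bases.

    A representative position is *uncertain* when no input contig other
    than the one that supplied that very position covers it — covering
    intervals carry the (source, contig) key of their query, and the
    supplier of each position is known from the representative's
    provenance segments.  Excluding only the position's own supplier
    (rather than all provenance) keeps the screen honest: a planted
    insertion is confirmed by nobody but the contig that carries it,
    while a legitimately extended representative remains covered by the
    contigs the extension came from.
    """
    w = config.end_window
    gaps: list[tuple[int, int]] = []
    pos = 0
    for seg in rep.segments:
        p0, p1 = pos, pos + len(seg)
        pos = p1
        key = (seg.source, seg.name)
        other = sorted(
            (max(s, p0), min(e, p1))
            for s, e, k in cover
            if k != key and s < p1 and e > p0
        )
        at = p0
        for s, e in other:
            if s > at:
                gaps.append((at, s))
            at = max(at, e)
        if at < p1:
            gaps.append((at, p1))
    # merge uncertain runs straddling segment boundaries
    merged_gaps: list[tuple[int, int]] = []
    for s, e in gaps:
        if merged_gaps and s <= merged_gaps[-1][1]:
            merged_gaps[-1] = (merged_gaps[-1][0], max(merged_gaps[-1][1], e))
        else:
            merged_gaps.append((s, e))
    bad = [(s, e) for s, e in merged_gaps if (e - s) >= w]
    if not bad:
        return [rep]
    pieces: list[WorkingContig] = []
    pos = 0
    for s, e in bad:
        if s > pos:
            pieces.append(rep.slice(pos, s, wid=f"{rep.id}.{len(pieces) + 1}"))
        pos = e
    if pos < rep.length:
        pieces.append(rep.slice(pos, rep.length, wid=f"{rep.id}.{len(pieces) + 1}"))
    if len(pieces) == 1:
        pieces = [replace(pieces[0], id=rep.id)]
    return [p for p in pieces if p.length >= config.min_contig_len]


# ---------------------------------------------------------------------------
# Phases 3 and 4 — overlap merging
# ---------------------------------------------------------------------------


def find_end_overlap(
    a: WorkingContig,
    b: WorkingContig,
    table: AlignmentTable,
    config: IntegrationConfig,
    min_overlap: float,
) -> OverlapCandidate | None:
    """Best proper end-to-end overlap between ``a`` and ``b``.

    A record qualifies when its identity exceeds ``extend_identity``,
    both aligned blocks lie within ``end_window`` of an extremity of
    their contig, the overhangs are on opposite sides, and the overlap
    is strictly longer than ``min_overlap``.  Among several, the longest
    overlap wins.
    """
    w = config.end_window
    best: OverlapCandidate | None = None
    for rec in table.for_pair(a.id, b.id):
        if rec.identity <= config.extend_identity:
            continue
        # frame: a forward; b reverse-complemented when strand is '-'
        qs, qe = rec.q_start, rec.q_end
        if rec.strand == "+":
            bts, bte = rec.t_start, rec.t_end
        else:
            bts, bte = b.length - rec.t_end, b.length - rec.t_start
        a_right_anchor = a.length - qe <= w
        b_left_anchor = bts <= w
        a_left_anchor = qs <= w
        b_right_anchor = b.length - bte <= w
        overlap = min(qe - qs, bte - bts)
        cand: OverlapCandidate | None = None
        # case 1: a's suffix overlaps (oriented) b's prefix -> a left of b
        if a_right_anchor and b_left_anchor:
            left_overhang = qs - bts
            right_overhang = (b.length - bte) - (a.length - qe)
            if left_overhang > 0 and right_overhang > 0:
                cand = OverlapCandidate(
                    a.id, b.id, rec, rec.strand, overlap,
                    a.length + b.length - overlap,
                )
        # case 2: (oriented) b's suffix overlaps a's prefix -> b left of a
        if cand is None and a_left_anchor and b_right_anchor:
            left_overhang = bts - qs
            right_overhang = (a.length - qe) - (b.length - bte)
            if left_overhang > 0 and right_overhang > 0:
                cand = OverlapCandidate(
                    b.id, a.id, rec, rec.strand, overlap,
                    a.length + b.length - overlap,
                )
        if cand is None or cand.overlap_len <= min_overlap:
            continue
        if best is None or cand.overlap_len > best.overlap_len:
            best = cand
    return best


def _merge_candidate(
    a: WorkingContig,
    b: WorkingContig,
    cand: OverlapCandidate,
    new_id: str,
) -> WorkingContig:
    """Merge two contigs on an end-to-end overlap candidate.

    The overlap copy is taken from the longer contig.  The right contig
    is reverse-complemented first when the overlap is on the minus
    strand.
    """
    rec = cand.record
    # frame matching find_end_overlap: a forward, b oriented by strand
    ob = b.reverse_complement() if rec.strand == "-" else b
    qs, qe = rec.q_start, rec.q_end
    if rec.strand == "+":
        bts, bte = rec.t_start, rec.t_end
    else:
        bts, bte = b.length - rec.t_end, b.length - rec.t_start
    if cand.left_id == a.id:
        left, right = a, ob
        l_end, l_start = qe, qs
        r_start, r_end = bts, bte
    else:
        left, right = ob, a
        l_end, l_start = bte, bts
        r_start, r_end = qs, qe
    # overlap copy comes from the longer contig
    if left.length >= right.length:
        head = left.slice(0, l_end)
        tail = right.slice(r_end, right.length) if r_end < right.length else None
    else:
        head = left.slice(0, l_start) if l_start > 0 else None
        tail = right.slice(r_start, right.length)
    parts = [p for p in (head, tail) if p is not None]
    return WorkingContig.concat(new_id, parts)


def _collect_repeat_evidence(
    table: AlignmentTable, config: IntegrationConfig
) -> RepeatEstimate:
    """Intervals aligned to >= 2 distinct non-overlapping regions.

    A record's query interval is repeat evidence when another
    high-identity record of the same query overlaps it by at least
    ``min_repeat_evidence_len`` while pointing at a distinct region —
    a different target, or the same target at intervals separated by
    more than ``min_repeat_evidence_len``.  Both intervals of such a
    pair are multi-mapped; R is the longest supporting interval.
    """
    mlen = config.min_repeat_evidence_len
    support: set[tuple[str, int, int]] = set()
    by_query: dict[str, list[AlignmentRecord]] = {}
    for rec in table.records:
        if rec.identity < config.extend_identity:
            continue
        if rec.q_span < mlen:
            continue
        by_query.setdefault(rec.query_id, []).append(rec)
    for qid in sorted(by_query):
        recs = by_query[qid]
        for i, r1 in enumerate(recs):
            for r2 in recs[i + 1 :]:
                if r1.target_id == r2.target_id:
                    sep = max(r1.t_start - r2.t_end, r2.t_start - r1.t_end)
                    if sep <= mlen:
                        continue
                lo = max(r1.q_start, r2.q_start)
                hi = min(r1.q_end, r2.q_end)
                if hi - lo >= mlen:
                    support.add((qid, r1.q_start, r1.q_end))
                    support.add((qid, r2.q_start, r2.q_end))
    ordered = sorted(support, key=lambda t: (-(t[2] - t[1]), t[0], t[1]))
    max_len = ordered[0][2] - ordered[0][1] if ordered else 0
    return RepeatEstimate(max_repeat_len=max_len, supporting_intervals=tuple(ordered))


def _merge_round(
    contigs: list[WorkingContig],
    config: IntegrationConfig,
    cache: AlignmentCache,
    min_overlap_for: callable,
    id_counter: list[int],
) -> tuple[list[WorkingContig], AlignmentTable, bool]:
    """Realign all-vs-all and apply the single best merge, if any."""
    table = align_sets(contigs, contigs, config.align, cache)
    by_id = {c.id: c for c in contigs}
    candidates: list[OverlapCandidate] = []
    ids = sorted(by_id)
    for i, ai in enumerate(ids):
        for bi in ids[i + 1 :]:
            a, b = by_id[ai], by_id[bi]
            cand = find_end_overlap(a, b, table, config, min_overlap_for(a, b))
            if cand is not None:
                candidates.append(cand)
    if not candidates:
        return contigs, table, False
    candidates.sort(key=lambda c: (-c.overlap_len, c.left_id, c.right_id))
    cand = candidates[0]
    a = by_id[cand.record.query_id]
    b = by_id[cand.record.target_id]
    id_counter[0] += 1
    merged = _merge_candidate(a, b, cand, f"m{id_counter[0]}")
    logger.debug(
        "merged %s + %s (overlap %d) -> %s (%d bp)",
        cand.left_id, cand.right_id, cand.overlap_len, merged.id, merged.length,
    )
    remaining = [c for c in contigs if c.id not in (a.id, b.id)]
    remaining.append(merged)
    remaining = _remove_contained(remaining, config, cache)
    return remaining, table, True


def phase3_iterative_merge(
    contigs: Sequence[WorkingContig],
    config: IntegrationConfig,
    cache: AlignmentCache | None = None,
) -> tuple[list[WorkingContig], RepeatEstimate]:
    """Greedy longest-overlap-first merging under the 30% rule, with
    full realignment after each merge, plus repeat-size estimation.

    Repeat evidence is collected from the final alignment state, after
    merging has converged: at that point genuinely adjacent contigs have
    been fused, so surviving multi-region alignments indicate repeats
    rather than ordinary staggered overlaps.
    """
    cache = cache or AlignmentCache()
    current = list(contigs)
    id_counter = [0]

    def min_overlap(a: WorkingContig, b: WorkingContig) -> float:
        return config.merge_frac * min(a.length, b.length)

    while True:
        current, table, merged = _merge_round(
            current, config, cache, min_overlap, id_counter
        )
        if not merged:
            break
    repeat = _collect_repeat_evidence(table, config)
    if repeat.max_repeat_len:
        logger.info("phase3: repeat estimate R = %d bp", repeat.max_repeat_len)
    return current, repeat


def phase4_merge(
    contigs: Sequence[WorkingContig],
    repeat: RepeatEstimate,
    config: IntegrationConfig,
    cache: AlignmentCache | None = None,
) -> list[WorkingContig]:
    """Final merging pass: only overlaps strictly longer than R qualify.

    With no repeat evidence (R = 0) a floor of
    ``min_repeat_evidence_len`` guards against spurious joins on
    arbitrarily short exact overlaps.
    """
    cache = cache or AlignmentCache()
    current = list(contigs)
    id_counter = [1000]
    floor = repeat.max_repeat_len or config.min_repeat_evidence_len

    def min_overlap(a: WorkingContig, b: WorkingContig) -> float:
        return float(floor)

    while True:
        current, _, merged = _merge_round(
            current, config, cache, min_overlap, id_counter
        )
        if not merged:
            break
    return current


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _normalize_assemblies(
    assemblies: Mapping[str, Sequence[Contig]] | Sequence[Sequence[Contig]],
) -> dict[str, list[Contig]]:
    if isinstance(assemblies, Mapping):
        return {k: list(v) for k, v in assemblies.items()}
    out: dict[str, list[Contig]] = {}
    for i, contigs in enumerate(assemblies):
        contigs = list(contigs)
        label = contigs[0].source if contigs and contigs[0].source else f"asm{i + 1}"
        if label in out:
            label = f"{label}_{i + 1}"
        out[label] = contigs
    return out


def integrate(
    assemblies: Mapping[str, Sequence[Contig]] | Sequence[Sequence[Contig]],
    config: IntegrationConfig | None = None,
) -> IntegrationResult:
    """Run the full four-phase integration.

    ``assemblies`` maps an assembly label to its contigs (or is a
    sequence of contig lists, labelled by their ``source``).  At least
    two assemblies are required; fewer than three draws a warning, as
    the screening phase relies on independent assemblies out-voting a
    misassembled one.  Returns the final contigs sorted by descending
    length plus a run report with per-phase counts, the repeat estimate
    and the provenance of every output base.
    """
    config = config or IntegrationConfig()
    named = _normalize_assemblies(assemblies)
    if len(named) < 2:
        raise ValueError("integration requires at least 2 assemblies")
    if len(named) < 3:
        logger.warning(
            "only %d assemblies supplied; at least 3 are recommended", len(named)
        )
    inputs: list[WorkingContig] = []
    for label in named:
        kept = 0
        for c in named[label]:
            if c.length < config.min_contig_len:
                continue
            wc = WorkingContig(
                id=f"{label}|{c.id}",
                seq=c.seq,
                segments=(Segment(label, c.id, 0, c.length),),
            )
            inputs.append(wc)
            kept += 1
        if kept == 0:
            raise ValueError(
                f"assembly {label!r} has no contigs of length >= {config.min_contig_len}"
            )
    cache = AlignmentCache()
    phase_outputs: dict[str, list[WorkingContig]] = {}

    reps = phase1_collapse(inputs, config, cache)
    phase_outputs["phase1"] = list(reps.contigs)
    logger.info("phase1: %d representative contig(s)", len(reps))

    screened = phase2_screen(reps, inputs, config, cache)
    phase_outputs["phase2"] = list(screened.contigs)
    logger.info("phase2: %d contig(s) after screening", len(screened))

    merged, repeat = phase3_iterative_merge(screened.contigs, config, cache)
    phase_outputs["phase3"] = list(merged)
    logger.info("phase3: %d contig(s), R = %d", len(merged), repeat.max_repeat_len)

    final_working = phase4_merge(merged, repeat, config, cache)
    final_working = sorted(
        final_working, key=lambda c: (-c.length, c.id)
    )
    phase_outputs["phase4"] = list(final_working)
    logger.info("phase4: %d contig(s)", len(final_working))

    final: list[Contig] = []
    provenance: dict[str, list[dict]] = {}
    for i, wc in enumerate(final_working, start=1):
        cid = f"contig_{i}"
        final.append(Contig(id=cid, seq=wc.seq, source="integrated"))
        provenance[cid] = [
            {
                "source": s.source,
                "contig": s.name,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
            }
            for s in wc.segments
        ]
    report = {
        "n_assemblies": len(named),
        "input_contigs": sum(len(v) for v in named.values()),
        "phases": {
            name: {
                "contigs": len(contigs),
                "bases": sum(c.length for c in contigs),
            }
            for name, contigs in phase_outputs.items()
        },
        "max_repeat_len": repeat.max_repeat_len,
        "output_contigs": len(final),
        "output_bases": sum(c.length for c in final),
        "provenance": provenance,
    }
    return IntegrationResult(
        contigs=final, repeat=repeat, report=report, phase_outputs=phase_outputs
    )
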