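"""Pairwise contig alignment.

The default engine is a maximal-exact-match (MEM) anchored
seed-and-extend aligner: all MEMs of at least ``min_mem`` bases are
enumerated between the query and the forward and reverse-complement
target, co-linear anchors are chained, inter-anchor gaps are closed with
edit-distance alignment (edlib), and the flanks are extended under the
same match/mismatch scoring that a local dynamic-programming aligner
would use.  Identity is exact — matched columns over total alignment
columns of the stitched alignment — and N never counts as a match.

External backends (``nucmer`` via show-coords, and ``blastn``) can be
selected instead; their tabular output is normalized by
:mod:`asmblend.formats` into the same :class:`AlignmentRecord` type.

The engine is fully deterministic: ties in chain scoring are broken by
(strand ``+`` first, smaller ``q_start``).
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, NamedTuple, Protocol, Sequence

import edlib

from .formats import (
    AlignmentRecord,
    AlignmentTable,
    Contig,
    parse_blast_tabular,
    parse_nucmer_coords,
    revcomp,
    write_fasta,
)

__all__ = [
    "AlignConfig",
    "AlignmentRecord",
    "AlignmentTable",
    "MEM",
    "align_pair",
    "align_sets",
    "alignment_rate",
    "find_mems",
    "chain_and_extend",
    "interval_union_length",
]


class SequenceLike(Protocol):
    id: str
    seq: str


@dataclass(frozen=True)
class AlignConfig:
    """Tunable knobs of the built-in engine.

    min_mem:    minimum maximal-exact-match seed length (bases).
    max_gap:    largest inter-anchor gap chained directly (bases).
    band:       maximum diagonal drift between chained anchors (bases).
    join_gap:   co-linear chains separated by at most this many bases are
                joined when the bridging alignment scores positive.
    flank_ext:  how far past the outermost anchors the ends are extended.
    match/mismatch/gap: scores used for flank extension and bridge
                acceptance; they mirror a simple local-alignment scoring.
    min_record_len: chains spanning fewer query bases are dropped.
    backend:    'builtin', 'nucmer' or 'blastn'.
    """

    min_mem: int = 20
    max_gap: int = 90
    band: int = 50
    join_gap: int = 600
    flank_ext: int = 400
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    min_record_len: int = 20
    backend: str = "builtin"


class MEM(NamedTuple):
    """Maximal exact match.

    For ``strand == '+'``: ``a[q_start:q_start+length] ==
    b[t_start:t_start+length]``.  For ``'-'``: ``a[q_start:...] ==
    revcomp(b[t_start:t_start+length])``.  N never matches anything, so
    MEMs are N-free.
    """

    q_start: int
    t_start: int
    length: int
    strand: str


@lru_cache(maxsize=192)
def _kmer_index(b: str, k: int) -> dict[str, list[int]]:
    """Position index of all N-free k-mers of ``b`` (memoized per target)."""
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    return index


@lru_cache(maxsize=192)
def _revcomp_cached(seq: str) -> str:
    return revcomp(seq)


def _scan_mems(a: str, b: str, index: dict[str, list[int]], k: int) -> list[tuple[int, int, int]]:
    """MEMs of length >= k between a and b given b's k-mer index."""
    out: list[tuple[int, int, int]] = []
    la, lb = len(a), len(b)
    get = index.get
    for i in range(la - k + 1):
        hits = get(a[i : i + k])
        if hits is None:
            continue
        for j in hits:
            # left-maximality: a seed extendable to the left belongs to a
            # MEM already emitted from the seed one position earlier
            if i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] != "N":
                continue
            qi, tj = i + k, j + k
            while qi < la and tj < lb and a[qi] == b[tj] and a[qi] != "N":
                qi += 1
                tj += 1
            out.append((i, j, qi - i))
    return out


def find_mems(a: str, b: str, min_len: int) -> list[MEM]:
    """All maximal exact matches of length >= min_len between ``a`` and
    ``b`` and between ``a`` and ``revcomp(b)`` (flagged ``'-'``).

    ``min_len`` must be at least 8.  Coordinates are forward-frame on
    both sequences (see :class:`MEM`).
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    index = _kmer_index(b, min_len)
    mems = [MEM(i, j, L, "+") for i, j, L in _scan_mems(a, b, index, min_len)]
    # a MEM against revcomp(b) is a MEM of revcomp(a) against b, flipped
    ra = _revcomp_cached(a)
    la = len(a)
    for i, j, L in _scan_mems(ra, b, index, min_len):
        mems.append(MEM(la - i - L, j, L, "-"))
    mems.sort()
    return mems


# ---------------------------------------------------------------------------
# Chaining and stitching
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _segment_stats(ga: str, gb: str) -> tuple[int, int, int]:
    """(matches, columns, score-numerator) for aligning two gap segments.

    Equal-length short segments are compared directly; otherwise edlib
    computes a global alignment.  N counts as a mismatch against
    anything, including another N.
    """
    if not ga and not gb:
        return 0, 0, 0
    if not ga or not gb:
        cols = max(len(ga), len(gb))
        return 0, cols, 0
    if len(ga) == len(gb) and len(ga) <= 40:
        m = sum(1 for x, y in zip(ga, gb) if x == y and x != "N")
        return m, len(ga), 0
    res = edlib.align(ga, gb, task="path", mode="NW")
    cig = res["cigar"] or ""
    m_cols = i_cols = d_cols = 0
    for num, op in _CIGAR_RE.findall(cig):
        n = int(num)
        if op in "M=X":
            m_cols += n
        elif op == "I":
            i_cols += n
        elif op == "D":
            d_cols += n
    columns = m_cols + i_cols + d_cols
    matches = columns - res["editDistance"]
    # N==N pairs are counted as matches by edlib; demote them
    if "N" in ga and "N" in gb and len(ga) == len(gb):
        matches -= sum(1 for x, y in zip(ga, gb) if x == "N" and y == "N")
    return max(matches, 0), columns, 0


def _extend_flank(a: str, b: str, q0: int, t0: int, direction: int,
                  cfg: AlignConfig) -> tuple[int, int, int]:
    """Greedy diagonal extension from (q0, t0).

    Walks outward comparing single bases under the configured scoring and
    stops at the score maximum (classic ungapped X-drop with an unlimited
    drop but bounded walk).  Returns (extension length, matches, columns)
    at the best-scoring point; zero-length when no extension improves the
    score.
    """
    best_len = 0
    best_matches = 0
    best_score = 0
    score = 0
    matches = 0
    la, lb = len(a), len(b)
    step = 0
    while step < cfg.flank_ext:
        if direction > 0:
            qi, ti = q0 + step, t0 + step
            if qi >= la or ti >= lb:
                break
        else:
            qi, ti = q0 - step - 1, t0 - step - 1
            if qi < 0 or ti < 0:
                break
        if a[qi] == b[ti] and a[qi] != "N":
            score += cfg.match
            matches += 1
        else:
            score += cfg.mismatch
        step += 1
        if score > best_score:
            best_score = score
            best_len = step
            best_matches = matches
    return best_len, best_matches, best_len


@dataclass
class _Chain:
    anchors: list[tuple[int, int, int]]  # (q_start, t_start, length)

    @property
    def q_start(self) -> int:
        return self.anchors[0][0]

    @property
    def q_end(self) -> int:
        return self.anchors[-1][0] + self.anchors[-1][2]

    @property
    def t_start(self) -> int:
        return self.anchors[0][1]

    @property
    def t_end(self) -> int:
        return self.anchors[-1][1] + self.anchors[-1][2]

    @property
    def coverage(self) -> int:
        return sum(L for _, _, L in self.anchors)


def _chain_anchors(anchors: list[tuple[int, int, int]], cfg: AlignConfig) -> list[_Chain]:
    """Greedy best-chain extraction over co-linear anchors.

    Anchors are chained when both gaps are within ``max_gap``, diagonal
    drift is within ``band`` and overlaps do not swallow an anchor.  The
    highest-coverage chain is extracted, its anchors retired, and the
    process repeats — so two genuinely distinct shared blocks yield two
    chains rather than one corrupt one.
    """
    if not anchors:
        return []
    anchors = sorted(anchors)
    chains: list[_Chain] = []
    alive = [True] * len(anchors)
    n = len(anchors)
    while True:
        best_score = [0] * n
        parent = [-1] * n
        order = [i for i in range(n) if alive[i]]
        if not order:
            break
        for idx, i in enumerate(order):
            qi, ti, li = anchors[i]
            best_score[i] = li
            for j in order[:idx]:
                qj, tj, lj = anchors[j]
                qg = qi - (qj + lj)
                tg = ti - (tj + lj)
                if qg > cfg.max_gap or tg > cfg.max_gap:
                    continue
                if qi <= qj or ti <= tj:
                    continue
                trim = max(0, -qg, -tg)
                if trim >= li:
                    continue
                if abs(qg - tg) > cfg.band:
                    continue
                cand = best_score[j] + li - trim
                if cand > best_score[i]:
                    best_score[i] = cand
                    parent[i] = j
        end = max(order, key=lambda i: (best_score[i], -anchors[i][0]))
        if best_score[end] < cfg.min_record_len:
            break
        chain: list[tuple[int, int, int]] = []
        k = end
        while k != -1:
            chain.append(anchors[k])
            k = parent[k]
        chain.reverse()
        ch = _Chain(chain)
        chains.append(ch)
        # retire anchors mostly inside the chain's footprint
        for i in order:
            qi, ti, li = anchors[i]
            q_ov = min(qi + li, ch.q_end) - max(qi, ch.q_start)
            t_ov = min(ti + li, ch.t_end) - max(ti, ch.t_start)
            if q_ov > li // 2 or t_ov > li // 2:
                alive[i] = False
    return chains


def _join_chains(chains: list[_Chain], a: str, b: str, cfg: AlignConfig) -> list[_Chain]:
    """Join co-linear chains across gaps too large for anchor chaining.

    Two chains are joined when they are in consistent order on both
    sequences, the gap is at most ``join_gap`` on each side, and the
    bridging alignment of the gap segments scores positive under the
    engine scoring — i.e. the gap looks like a noisy continuation of the
    same alignment, not an unrelated block.
    """
    chains = sorted(chains, key=lambda c: (c.q_start, c.t_start))
    out: list[_Chain] = []
    for ch in chains:
        if out:
            prev = out[-1]
            qg = ch.q_start - prev.q_end
            tg = ch.t_start - prev.t_end
            if 0 <= qg <= cfg.join_gap and 0 <= tg <= cfg.join_gap:
                ga = a[prev.q_end : ch.q_start]
                gb = b[prev.t_end : ch.t_start]
                m, cols, _ = _segment_stats(ga, gb)
                mismatches = min(len(ga), len(gb)) - m
                indels = cols - min(len(ga), len(gb))
                score = m * cfg.match + mismatches * cfg.mismatch + indels * cfg.gap
                if cols == 0 or score > 0:
                    prev.anchors.extend(ch.anchors)
                    continue
        out.append(ch)
    return out


def _stitch(chain: _Chain, a: str, b: str, cfg: AlignConfig) -> tuple[int, int, int, int, int, int]:
    """Compute (q0, q1, t0, t1, matches, columns) for a chain, including
    flank extension."""
    matches = 0
    columns = 0
    prev_qe = prev_te = None
    for qs, ts, L in chain.anchors:
        if prev_qe is not None:
            trim = max(0, prev_qe - qs, prev_te - ts)
            qs += trim
            ts += trim
            L -= trim
            if L <= 0:
                continue
            m, cols, _ = _segment_stats(a[prev_qe:qs], b[prev_te:ts])
            matches += m
            columns += cols
        matches += L
        columns += L
        prev_qe, prev_te = qs + L, ts + L
    q0, t0 = chain.q_start, chain.t_start
    q1, t1 = prev_qe, prev_te
    ext, m, cols = _extend_flank(a, b, q0, t0, -1, cfg)
    q0 -= ext
    t0 -= ext
    matches += m
    columns += cols
    ext, m, cols = _extend_flank(a, b, q1, t1, +1, cfg)
    q1 += ext
    t1 += ext
    matches += m
    columns += cols
    return q0, q1, t0, t1, matches, columns


def chain_and_extend(
    anchors: Sequence[MEM],
    a: str,
    b: str,
    config: AlignConfig | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> list[AlignmentRecord]:
    """Turn MEM anchors into alignment records.

    Co-linear anchors are chained per strand, chains separated by
    bridgeable gaps are joined, gap segments are closed with
    edit-distance alignment and flanks are extended under local scoring.
    Redundant records (footprint overlapping a better record) are
    suppressed, keeping the best ``identity x length``.
    """
    cfg = config or AlignConfig()
    records: list[AlignmentRecord] = []
    n = len(b)
    for strand in "+-":
        if strand == "+":
            frame_anchors = [(m.q_start, m.t_start, m.length) for m in anchors if m.strand == "+"]
            bo = b
        else:
            frame_anchors = [
                (m.q_start, n - m.t_start - m.length, m.length)
                for m in anchors
                if m.strand == "-"
            ]
            bo = revcomp(b)
        chains = _chain_anchors(frame_anchors, cfg)
        chains = _join_chains(chains, a, bo, cfg)
        for ch in chains:
            q0, q1, t0, t1, matches, columns = _stitch(ch, a, bo, cfg)
            if q1 - q0 < cfg.min_record_len or columns == 0:
                continue
            if strand == "+":
                ts, te = t0, t1
            else:
                ts, te = n - t1, n - t0
            records.append(
                AlignmentRecord(
                    query_id=query_id,
                    target_id=target_id,
                    q_start=q0,
                    q_end=q1,
                    t_start=ts,
                    t_end=te,
                    strand=strand,
                    identity=matches / columns,
                    aln_len=columns,
                )
            )
    # suppress redundant records: best identity x length first
    records.sort(key=lambda r: (-r.identity * r.aln_len, r.strand, r.q_start))
    kept: list[AlignmentRecord] = []
    for rec in records:
        redundant = False
        for k in kept:
            q_ov = min(rec.q_end, k.q_end) - max(rec.q_start, k.q_start)
            t_ov = min(rec.t_end, k.t_end) - max(rec.t_start, k.t_start)
            if q_ov > 0.5 * rec.q_span and t_ov > 0.5 * rec.t_span:
                redundant = True
                break
        if not redundant:
            kept.append(rec)
    kept.sort(key=lambda r: (r.q_start, r.t_start, r.strand))
    return kept


def align_pair(
    a: SequenceLike,
    b: SequenceLike,
    config: AlignConfig | None = None,
) -> list[AlignmentRecord]:
    """Align one query contig against one target contig (builtin engine)."""
    cfg = config or AlignConfig()
    mems = find_mems(a.seq, b.seq, cfg.min_mem)
    return chain_and_extend(mems, a.seq, b.seq, cfg, query_id=a.id, target_id=b.id)


# ---------------------------------------------------------------------------
# Set-level alignment
# ---------------------------------------------------------------------------


class AlignmentCache:
    """Memoizes pair alignments by sequence content.

    Records are stored id-free and re-labelled on retrieval, so renaming
    a contig does not defeat the cache.  Re-alignment after an iterative
    merge therefore only pays for pairs involving fresh sequence.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], list[AlignmentRecord]] = {}

    def get_or_align(self, a: SequenceLike, b: SequenceLike, cfg: AlignConfig) -> list[AlignmentRecord]:
        key = (a.seq, b.seq)
        recs = self._store.get(key)
        if recs is None:
            recs = [
                replace(r, query_id="", target_id="")
                for r in align_pair(_Anon(a.seq), _Anon(b.seq), cfg)
            ]
            self._store[key] = recs
        return [replace(r, query_id=a.id, target_id=b.id) for r in recs]


@dataclass(frozen=True)
class _Anon:
    seq: str
    id: str = ""


def _external_backend(
    queries: Sequence[SequenceLike],
    targets: Sequence[SequenceLike],
    cfg: AlignConfig,
) -> list[AlignmentRecord]:
    qset = [Contig(id=q.id, seq=q.seq) for q in queries]
    tset = [Contig(id=t.id, seq=t.seq) for t in targets]
    with tempfile.TemporaryDirectory(prefix="asmblend_") as tmp:
        qpath = Path(tmp) / "query.fa"
        tpath = Path(tmp) / "target.fa"
        write_fasta(qset, qpath)
        write_fasta(tset, tpath)
        if cfg.backend == "blastn":
            if shutil.which("blastn") is None:
                raise RuntimeError(
                    "blastn executable not found; select the 'builtin' aligner backend"
                )
            out = subprocess.run(
                ["blastn", "-query", str(qpath), "-subject", str(tpath), "-outfmt", "6"],
                capture_output=True,
                text=True,
                check=True,
            )
            return parse_blast_tabular(out.stdout)
        if cfg.backend == "nucmer":
            if shutil.which("nucmer") is None or shutil.which("show-coords") is None:
                raise RuntimeError(
                    "nucmer/show-coords executables not found; select the "
                    "'builtin' aligner backend"
                )
            prefix = str(Path(tmp) / "aln")
            subprocess.run(
                ["nucmer", "--maxmatch", "-p", prefix, str(tpath), str(qpath)],
                capture_output=True,
                check=True,
            )
            out = subprocess.run(
                ["show-coords", "-rcl", "-H", prefix + ".delta"],
                capture_output=True,
                text=True,
                check=True,
            )
            return parse_nucmer_coords(out.stdout)
    raise ValueError(f"unknown aligner backend {cfg.backend!r}")


def align_sets(
    queries: Sequence[SequenceLike],
    targets: Sequence[SequenceLike],
    config: AlignConfig | None = None,
    cache: AlignmentCache | None = None,
) -> AlignmentTable:
    """All-vs-all alignment of a query contig set against a target set.

    Pairs sharing the same id are skipped (self pairs when both sets
    share members).  Record order is deterministic.
    """
    cfg = config or AlignConfig()
    query_lengths = {q.id: len(q.seq) for q in queries}
    target_lengths = {t.id: len(t.seq) for t in targets}
    if len(query_lengths) != len(queries) or len(target_lengths) != len(targets):
        raise ValueError("duplicate ids within a contig set")
    if cfg.backend != "builtin":
        records = [
            r
            for r in _external_backend(queries, targets, cfg)
            if r.query_id != r.target_id
        ]
        return AlignmentTable(records, query_lengths, target_lengths)
    cache = cache or AlignmentCache()
    records: list[AlignmentRecord] = []
    for q in queries:
        for t in targets:
            if q.id == t.id:
                continue
            records.extend(cache.get_or_align(q, t, cfg))
    return AlignmentTable(records, query_lengths, target_lengths)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def alignment_rate(
    table: AlignmentTable, query_id: str, target_id: str | None = None
) -> float:
    """Fraction of the query covered by the union of its aligned intervals.

    Restricted to one target when ``target_id`` is given — the
    convention used for containment, where the major portion of a contig
    must lie within a single representative.  Identity filtering is the
    caller's job (via :meth:`AlignmentTable.filtered`).
    """
    if query_id not in table.query_lengths:
        raise KeyError(f"unknown query id {query_id!r}")
    if target_id is None:
        recs = table.for_query(query_id)
    else:
        recs = table.for_pair(query_id, target_id)
    if not recs:
        return 0.0
    covered = interval_union_length((r.q_start, r.q_end) for r in recs)
    return covered / table.query_lengths[query_id]
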