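"""FASTA I/O and parsers for external aligner tables.

Everything downstream of this module works in a single coordinate
convention: 0-based, half-open intervals on both query and target, with
the strand carried as a flag.  The two external dialects the package can
consume (MUMmer ``show-coords`` tabular text and BLAST ``-outfmt 6``)
use 1-based inclusive coordinates and encode reverse-strand hits by
swapping interval endpoints; both are normalized here, at the parser
boundary.

A record with ``strand == '-'`` means ``query[q_start:q_end]`` matches
the reverse complement of ``target[t_start:t_end]``; intervals always
satisfy ``start < end`` in the forward frame of their own sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA records or unparseable alignment rows."""


# ---------------------------------------------------------------------------
# Contig
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """One assembled sequence with provenance.

    Parameters
    ----------
    id :
        Unique label, the first whitespace-delimited token of the FASTA
        header.
    seq :
        Upper-case DNA over ``{A, C, G, T, N}``.
    source :
        Label of the input assembly the contig came from; ``(source, id)``
        is unique within a run.
    description :
        Full FASTA header, retained for round-tripping but never used
        for identity.
    """

    id: str
    seq: str
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.id!r}: characters outside ACGTN alphabet: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "Contig":
        return replace(self, seq=revcomp(self.seq))


def read_fasta(path: str | Path, source: str | None = None) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`.

    Multi-line sequences are concatenated and lowercase is folded to
    upper.  ``source`` defaults to the file stem.  An empty file yields
    an empty list; a record containing a character outside ACGTN (after
    folding) raises :class:`FormatError` naming the record.
    """
    path = Path(path)
    if source is None:
        source = path.stem
    contigs: list[Contig] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            contigs.append(
                Contig(id=rec.id, seq=seq, source=source, description=rec.description)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return contigs


def write_fasta(
    contigs: Sequence[Contig], path: str | Path, width: int = 60
) -> None:
    """Write contigs to FASTA with ``width`` bases per line.

    Raises :class:`FormatError` on duplicate ids.  Round-trips exactly
    through :func:`read_fasta`.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    seen: set[str] = set()
    for c in contigs:
        if c.id in seen:
            raise FormatError(f"duplicate contig id {c.id!r}")
        seen.add(c.id)
    with open(path, "w") as fh:
        for c in contigs:
            header = c.description if c.description.startswith(c.id) else c.id
            fh.write(f">{header}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """One local alignment block between a query and a target contig.

    ``identity`` is the matched-columns fraction in ``[0, 1]``;
    ``aln_len`` counts alignment columns including gaps, so
    ``aln_len >= max(q_end - q_start, t_end - t_start)`` up to gap slack.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"
    identity: float = 1.0
    aln_len: int = 0

    def __post_init__(self) -> None:
        if self.q_end - self.q_start < 1 or self.t_end - self.t_start < 1:
            raise ValueError(f"degenerate alignment interval: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start


class AlignmentTable:
    """All alignment records for a query set vs a target set.

    Records are kept in deterministic order
    ``(query_id, target_id, q_start, t_start)`` and are queryable by
    query id or by (query, target) pair.  Every record id must appear in
    the corresponding length map.
    """

    def __init__(
        self,
        records: Iterable[AlignmentRecord],
        query_lengths: Mapping[str, int],
        target_lengths: Mapping[str, int],
    ) -> None:
        self.records: list[AlignmentRecord] = sorted(
            records,
            key=lambda r: (r.query_id, r.target_id, r.q_start, r.t_start, r.strand),
        )
        self.query_lengths = dict(query_lengths)
        self.target_lengths = dict(target_lengths)
        self._by_query: dict[str, list[AlignmentRecord]] = {}
        self._by_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
        for rec in self.records:
            if rec.query_id not in self.query_lengths:
                raise KeyError(f"record query {rec.query_id!r} not in query_lengths")
            if rec.target_id not in self.target_lengths:
                raise KeyError(f"record target {rec.target_id!r} not in target_lengths")
            self._by_query.setdefault(rec.query_id, []).append(rec)
            self._by_pair.setdefault((rec.query_id, rec.target_id), []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records)

    def for_query(self, query_id: str) -> list[AlignmentRecord]:
        if query_id not in self.query_lengths:
            raise KeyError(f"unknown query id {query_id!r}")
        return list(self._by_query.get(query_id, []))

    def for_pair(self, query_id: str, target_id: str) -> list[AlignmentRecord]:
        return list(self._by_pair.get((query_id, target_id), []))

    def filtered(self, min_identity: float, strict: bool = False) -> "AlignmentTable":
        """New table keeping records at / above the identity floor."""
        if strict:
            keep = [r for r in self.records if r.identity > min_identity]
        else:
            keep = [r for r in self.records if r.identity >= min_identity]
        return AlignmentTable(keep, self.query_lengths, self.target_lengths)


# ---------------------------------------------------------------------------
# External dialect: NUCmer show-coords
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"^-?\d+$")


def parse_nucmer_coords(text: str) -> list[AlignmentRecord]:
    """Parse ``show-coords -rcl``-style tabular text.

    Column layout per data row (``|`` separators stripped):
    ``S1 E1 S2 E2 LEN1 LEN2 %IDY [LENR LENQ [COVR COVQ]] RTAG QTAG``
    where S/E are 1-based inclusive, reference first.  The reference is
    stored as the record *target* and the query as *query*; a row with
    ``S2 > E2`` is a reverse-strand hit and is normalized to a forward
    interval with ``strand='-'``.
    """
    records: list[AlignmentRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = [t for t in line.replace("|", " ").split() if t]
        if not _INT_RE.match(tokens[0]):
            continue  # header / separator line
        if len(tokens) not in (9, 11, 13):
            raise FormatError(
                f"show-coords row {lineno}: expected 9, 11 or 13 fields, "
                f"got {len(tokens)}: {raw!r}"
            )
        try:
            s1, e1, s2, e2 = (int(t) for t in tokens[:4])
            idy = float(tokens[6])
        except ValueError:
            raise FormatError(f"show-coords row {lineno}: unparseable: {raw!r}") from None
        rtag, qtag = tokens[-2], tokens[-1]
        aln_len = max(int(tokens[4]), int(tokens[5]))
        t_start, t_end = s1 - 1, e1
        if s2 <= e2:
            strand, q_start, q_end = "+", s2 - 1, e2
        else:
            strand, q_start, q_end = "-", e2 - 1, s2
        records.append(
            AlignmentRecord(
                query_id=qtag,
                target_id=rtag,
                q_start=q_start,
                q_end=q_end,
                t_start=t_start,
                t_end=t_end,
                strand=strand,
                identity=idy / 100.0,
                aln_len=aln_len,
            )
        )
    return records


def write_nucmer_coords(records: Iterable[AlignmentRecord]) -> str:
    """Serialize records back to the show-coords dialect (for round-trips)."""
    lines = ["[S1] [E1] | [S2] [E2] | [LEN 1] [LEN 2] | [% IDY] | [TAGS]"]
    for r in records:
        s1, e1 = r.t_start + 1, r.t_end
        if r.strand == "+":
            s2, e2 = r.q_start + 1, r.q_end
        else:
            s2, e2 = r.q_end, r.q_start + 1
        len1, len2 = r.t_span, r.q_span
        lines.append(
            f"{s1} {e1} | {s2} {e2} | {len1} {len2} | "
            f"{r.identity * 100:.2f} | {r.target_id}\t{r.query_id}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# External dialect: BLAST outfmt 6
# ---------------------------------------------------------------------------


def parse_blast_tabular(text: str) -> list[AlignmentRecord]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore (1-based inclusive).  The subject is the
    record target.  ``sstart > send`` marks a reverse-strand hit.
    """
    records: list[AlignmentRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 1:
            cols = line.split()
        if len(cols) != 12:
            raise FormatError(
                f"blast tabular row {lineno}: expected 12 columns, got {len(cols)}"
            )
        qid, sid = cols[0], cols[1]
        try:
            pident = float(cols[2])
            length = int(cols[3])
            qs, qe, ss, se = (int(c) for c in cols[6:10])
        except ValueError:
            raise FormatError(f"blast tabular row {lineno}: unparseable: {raw!r}") from None
        q_start, q_end = qs - 1, qe
        if ss <= se:
            strand, t_start, t_end = "+", ss - 1, se
        else:
            strand, t_start, t_end = "-", se - 1, ss
        records.append(
            AlignmentRecord(
                query_id=qid,
                target_id=sid,
                q_start=q_start,
                q_end=q_end,
                t_start=t_start,
                t_end=t_end,
                strand=strand,
                identity=pident / 100.0,
                aln_len=length,
            )
        )
    return records
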