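"""Assembly evaluation metrics.

Self-computed counterparts of the usual draft-assembly report card:
contig counts, total bases, N50 and maximum contig length; the
reference-based percentages of missed and extra bases; the count of
reference coding sequences recovered intact (covered >99% at >99%
identity by their best contig hit); and assembly-error counts — indels
of at least 5 bases, inversions, and relocations — derived from chained
contig-to-reference alignments.

All alignments run through :mod:`asmblend.align`.  For error counting
the chain gap ceiling is lowered so that any indel of ``min_indel``
bases or more breaks the chain into adjacent co-linear blocks, where
the discrepancy is classified; smaller indels stay inside a block and
are ignored, matching the convention of counting only indels >= 5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

from .align import (
    AlignConfig,
    AlignmentCache,
    align_sets,
    interval_union_length,
)
from .formats import Contig

__all__ = [
    "EvaluationReport",
    "n50",
    "coverage_metrics",
    "blast_intact_cds",
    "count_assembly_errors",
    "split_at_ns",
    "evaluation_report",
]


@dataclass(frozen=True)
class EvaluationReport:
    num_contigs: int
    assembly_bases: int
    n50: int
    max_contig: int
    pct_missed: float
    pct_extra: float
    intact_cds: int = 0
    indel_ge5: int = 0
    inversion: int = 0
    relocation: int = 0

    def to_dict(self) -> dict:
        return {
            "num_contigs": self.num_contigs,
            "assembly_bases": self.assembly_bases,
            "n50": self.n50,
            "max_contig": self.max_contig,
            "pct_missed": self.pct_missed,
            "pct_extra": self.pct_extra,
            "intact_cds": self.intact_cds,
            "assembly_errors": {
                "indel_ge5": self.indel_ge5,
                "inversion": self.inversion,
                "relocation": self.relocation,
            },
        }


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to at least half
    the total assembly size."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


def coverage_metrics(
    assembly: Sequence[Contig],
    reference: Sequence[Contig],
    config: AlignConfig | None = None,
    min_identity: float = 0.95,
    cache: AlignmentCache | None = None,
) -> tuple[float, float]:
    """(%missed, %extra) of an assembly against a reference genome.

    %missed: reference bases covered by no assembly alignment at
    identity >= ``min_identity``, as a percentage of reference length.
    %extra: assembly bases aligning nowhere on the reference, as a
    percentage of assembly bases.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    cfg = config or AlignConfig()
    table = align_sets(list(assembly), list(reference), cfg, cache)
    ref_len = sum(c.length for c in reference)
    asm_len = sum(c.length for c in assembly)
    recs = [r for r in table.records if r.identity >= min_identity]
    ref_cov = 0
    for ref_contig in reference:
        ref_cov += interval_union_length(
            (r.t_start, r.t_end) for r in recs if r.target_id == ref_contig.id
        )
    asm_cov = 0
    for contig in assembly:
        asm_cov += interval_union_length(
            (r.q_start, r.q_end) for r in recs if r.query_id == contig.id
        )
    pct_missed = 100.0 * (ref_len - ref_cov) / ref_len
    pct_extra = 100.0 * (asm_len - asm_cov) / asm_len if asm_len else 0.0
    return pct_missed, pct_extra


def blast_intact_cds(
    cds_set: Sequence[Contig],
    contigs: Sequence[Contig],
    config: AlignConfig | None = None,
    min_rate: float = 0.99,
    min_identity: float = 0.99,
    cache: AlignmentCache | None = None,
) -> int:
    """Count CDS whose best contig hit covers more than ``min_rate`` of
    the CDS length at identity above ``min_identity``.

    Each CDS is counted at most once, against its best-covering contig.
    """
    if not cds_set:
        raise ValueError("cds_set must be non-empty")
    cfg = config or AlignConfig()
    table = align_sets(list(cds_set), list(contigs), cfg, cache)
    count = 0
    for cds in cds_set:
        best = 0.0
        for contig in contigs:
            recs = [
                r
                for r in table.for_pair(cds.id, contig.id)
                if r.identity > min_identity
            ]
            if not recs:
                continue
            covered = interval_union_length((r.q_start, r.q_end) for r in recs)
            best = max(best, covered / cds.length)
        if best > min_rate:
            count += 1
    return count


def count_assembly_errors(
    assembly: Sequence[Contig],
    reference: Sequence[Contig],
    config: AlignConfig | None = None,
    min_indel: int = 5,
    relocation_tol: int = 1000,
    min_block: int = 50,
    min_identity: float = 0.95,
) -> tuple[int, int, int]:
    """(indel_ge5, inversion, relocation) from contig-to-reference blocks.

    Contigs are aligned with the chain gap ceiling lowered to
    ``min_indel - 1`` so indels of at least ``min_indel`` bases split
    the alignment into adjacent co-linear blocks.  Walking each contig's
    blocks in contig order: opposite-strand neighbours count as an
    inversion; same-strand neighbours whose reference placement is out
    of order or displaced by more than ``relocation_tol`` count as a
    relocation; otherwise an unbalanced gap of at least ``min_indel``
    bases counts as an indel.  A wholly reverse-complemented contig has
    same-strand blocks throughout and is no error.
    """
    cfg = config or AlignConfig()
    cfg = replace(cfg, max_gap=min_indel - 1, join_gap=0, band=min(cfg.band, 25))
    table = align_sets(list(assembly), list(reference), cfg)
    indel = inversion = relocation = 0
    for contig in assembly:
        recs = [
            r
            for r in table.for_query(contig.id)
            if r.identity >= min_identity and r.q_span >= min_block
        ]
        recs.sort(key=lambda r: (r.q_start, r.t_start))
        for r1, r2 in zip(recs, recs[1:]):
            if r1.target_id != r2.target_id:
                relocation += 1
                continue
            if r1.strand != r2.strand:
                inversion += 1
                continue
            dq = r2.q_start - r1.q_end
            if r1.strand == "+":
                dt = r2.t_start - r1.t_end
            else:
                dt = r1.t_start - r2.t_end
            if dt < -relocation_tol or abs(dt - dq) > relocation_tol:
                relocation += 1
            elif abs(dt - dq) >= min_indel:
                indel += 1
    return indel, inversion, relocation


_N_RUN = re.compile(r"N+")


def split_at_ns(contigs: Sequence[Contig], n: int = 10) -> list[Contig]:
    """Partition contigs at runs of more than ``n`` Ns.

    The pre-evaluation fix for assemblies that pad joins with uncalled
    bases; pieces inherit the parent id with a ``.k`` suffix.
    """
    out: list[Contig] = []
    for contig in contigs:
        pieces = []
        pos = 0
        for m in _N_RUN.finditer(contig.seq):
            if m.end() - m.start() > n:
                if m.start() > pos:
                    pieces.append(contig.seq[pos : m.start()])
                pos = m.end()
        if pos < contig.length:
            pieces.append(contig.seq[pos:])
        if len(pieces) == 1 and pieces[0] == contig.seq:
            out.append(contig)
        else:
            for k, seq in enumerate(pieces, start=1):
                out.append(replace(contig, id=f"{contig.id}.{k}", seq=seq))
    return out


def evaluation_report(
    assembly: Sequence[Contig],
    reference: Sequence[Contig] | None = None,
    cds: Sequence[Contig] | None = None,
    config: AlignConfig | None = None,
) -> EvaluationReport:
    """Full report for one assembly, reference-based fields included
    when a reference is supplied."""
    lengths = [c.length for c in assembly]
    pct_missed = pct_extra = 0.0
    intact = 0
    errors = (0, 0, 0)
    if reference:
        pct_missed, pct_extra = coverage_metrics(assembly, reference, config)
        errors = count_assembly_errors(assembly, reference, config)
    if cds:
        intact = blast_intact_cds(cds, assembly, config)
    return EvaluationReport(
        num_contigs=len(assembly),
        assembly_bases=sum(lengths),
        n50=n50(lengths) if lengths else 0,
        max_contig=max(lengths) if lengths else 0,
        pct_missed=round(pct_missed, 2),
        pct_extra=round(pct_extra, 2),
        intact_cds=intact,
        indel_ge5=errors[0],
        inversion=errors[1],
        relocation=errors[2],
    )
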