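"""Deterministic synthetic-assembly fixture generation.

This module is the test substrate for the integrator: it simulates a
bacterial genome, fragments it into several complete, error-free,
staggered tilings (one per virtual assembler), and optionally corrupts
contigs the way real draft assemblies go wrong — misjoins fusing two
distant loci into a chimera, insertions of novel sequence seen in no
other assembly, and tandem/dispersed repeats planted into the genome.

Every operation is fully determined by its seed, and each generated
contig is described in a machine-readable :class:`TruthTable` whose
intervals are exact 0-based half-open genome coordinates.  What the
generator deliberately does *not* emulate: sequencing errors inside
fragments (fragments are error-free by default, so algorithmic
properties can be asserted exactly), coverage fluctuation, and
assembler-specific artifacts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import Contig, revcomp

__all__ = [
    "TruthEntry",
    "TruthTable",
    "simulate_genome",
    "plant_repeat",
    "fragment_into_assemblies",
    "assemblies_from_breakpoints",
    "inject_misjoin",
    "inject_insertion",
    "standard_fixture",
    "repeat_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated contig.

    ``intervals``/``strands`` list the genome blocks concatenated to
    form the contig, in contig order.  Clean contigs have exactly one
    interval; chimeras two non-adjacent ones.  For insertion-bearing
    contigs ``insert_offset``/``insert_len`` locate the novel sequence
    within the contig.
    """

    source: str
    id: str
    intervals: tuple[tuple[int, int], ...]
    strands: tuple[str, ...]
    tag: str = "clean"  # clean | chimera | insertion
    insert_offset: int = -1
    insert_len: int = 0

    def __post_init__(self) -> None:
        if self.tag == "clean" and len(self.intervals) != 1:
            raise ValueError("clean contigs carry exactly one genome interval")
        if self.tag == "chimera" and len(self.intervals) != 2:
            raise ValueError("chimeras carry exactly two genome intervals")


@dataclass
class TruthTable:
    genome_len: int
    entries: list[TruthEntry] = field(default_factory=list)

    def for_source(self, source: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.source == source]

    def lookup(self, source: str, contig_id: str) -> TruthEntry:
        for e in self.entries:
            if e.source == source and e.id == contig_id:
                return e
        raise KeyError((source, contig_id))

    def to_tsv(self) -> str:
        lines = ["#source\tid\tintervals\tstrands\ttag\tinsert_offset\tinsert_len"]
        for e in self.entries:
            ivals = ",".join(f"{s}-{t}" for s, t in e.intervals)
            lines.append(
                f"{e.source}\t{e.id}\t{ivals}\t{''.join(e.strands)}\t{e.tag}"
                f"\t{e.insert_offset}\t{e.insert_len}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, genome_len: int) -> "TruthTable":
        table = cls(genome_len=genome_len)
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            src, cid, ivals, strands, tag, off, ilen = line.split("\t")
            intervals = tuple(
                tuple(int(x) for x in part.split("-")) for part in ivals.split(",")
            )
            table.entries.append(
                TruthEntry(
                    source=src,
                    id=cid,
                    intervals=intervals,  # type: ignore[arg-type]
                    strands=tuple(strands),
                    tag=tag,
                    insert_offset=int(off),
                    insert_len=int(ilen),
                )
            )
        return table


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome of the given length and GC content."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def plant_repeat(
    genome: str, repeat_len: int, positions: Sequence[int], seed: int = 0
) -> tuple[str, str]:
    """Overwrite the genome with one random repeat unit at each locus.

    Positions are unit start coordinates; at least two non-overlapping
    loci are required.  Returns the modified genome and the unit.
    """
    if len(positions) < 2:
        raise ValueError("a repeat needs at least 2 loci")
    pos = sorted(positions)
    for p, q in zip(pos, pos[1:]):
        if q < p + repeat_len:
            raise ValueError(f"repeat loci {p} and {q} overlap (unit {repeat_len} bp)")
    if pos[-1] + repeat_len > len(genome):
        raise ValueError("repeat locus extends past genome end")
    rng = np.random.default_rng(seed)
    unit = "".join(rng.choice(_BASES, size=repeat_len))
    out = list(genome)
    for p in pos:
        out[p : p + repeat_len] = unit
    return "".join(out), unit


def _tile(
    genome_len: int, breakpoints: Sequence[int]
) -> list[tuple[int, int]]:
    bounds = [0, *sorted(b for b in breakpoints if 0 < b < genome_len), genome_len]
    return [(s, e) for s, e in zip(bounds, bounds[1:]) if e > s]


def assemblies_from_breakpoints(
    genome: str,
    breakpoints: Mapping[str, Sequence[int]],
    seed: int = 0,
) -> tuple[dict[str, list[Contig]], TruthTable]:
    """Build complete error-free tilings from explicit breakpoints.

    Each assembly tiles ``[0, len(genome))`` with non-overlapping
    fragments cut at its own breakpoints; strand is assigned at random
    per contig.  Used both by :func:`fragment_into_assemblies` and by
    layouts that need controlled breakpoints (e.g. forcing contig ends
    inside a planted repeat).
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable(genome_len=len(genome))
    assemblies: dict[str, list[Contig]] = {}
    for source in breakpoints:
        contigs: list[Contig] = []
        for i, (s, e) in enumerate(_tile(len(genome), breakpoints[source]), start=1):
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome[s:e] if strand == "+" else revcomp(genome[s:e])
            cid = f"c{i}"
            contigs.append(Contig(id=cid, seq=seq, source=source))
            truth.entries.append(
                TruthEntry(source=source, id=cid, intervals=((s, e),), strands=(strand,))
            )
        assemblies[source] = contigs
    return assemblies, truth


def fragment_into_assemblies(
    genome: str,
    n_assemblies: int = 3,
    mean_len: int = 8000,
    min_overlap_frac: float = 0.35,
    seed: int = 0,
) -> tuple[dict[str, list[Contig]], TruthTable]:
    """Fragment one genome into several staggered error-free tilings.

    Assembly ``i`` breaks the genome every ``mean_len`` bases with a
    per-assembly phase offset plus a small jitter, so that fragments
    which are adjacent across assemblies overlap by more than
    ``min_overlap_frac`` of the smaller fragment.  Raises when the
    requested parameters cannot satisfy that contract.
    """
    if n_assemblies < 2:
        raise ValueError("need at least 2 assemblies")
    glen = len(genome)
    if mean_len >= glen:
        raise ValueError("mean fragment length must be smaller than the genome")
    rng = np.random.default_rng(seed)
    # evenly phased offsets keep cross-assembly overlaps comfortably
    # above the contract even after jitter
    phases = [(i + 0.5) / n_assemblies for i in range(n_assemblies)]
    jitter = 0.05 * mean_len
    breakpoints: dict[str, list[int]] = {}
    for i in range(n_assemblies):
        src = f"asm{i + 1}"
        bps = []
        b = phases[i] * mean_len
        while b < glen:
            bps.append(int(round(b + rng.uniform(-jitter, jitter))))
            b += mean_len
        breakpoints[src] = bps
    assemblies, truth = assemblies_from_breakpoints(
        genome, breakpoints, seed=int(rng.integers(2**31 - 1))
    )
    _check_overlap_contract(truth, min_overlap_frac)
    return assemblies, truth


def _check_overlap_contract(truth: TruthTable, min_overlap_frac: float) -> None:
    """Every pair of truth-adjacent cross-assembly fragments must overlap
    by more than ``min_overlap_frac`` of the smaller one."""
    intervals = [
        (e.intervals[0], e.source) for e in truth.entries if e.tag == "clean"
    ]
    intervals.sort()
    for ((s1, e1), src1), ((s2, e2), src2) in zip(intervals, intervals[1:]):
        if src1 == src2:
            continue
        if s2 >= e1:  # disjoint cross-assembly neighbours: no path
            raise ValueError(
                f"fragmentation violates the overlap contract near {e1}"
            )
        ov = min(e1, e2) - s2
        smaller = min(e1 - s1, e2 - s2)
        if ov <= min_overlap_frac * smaller:
            raise ValueError(
                f"cross-assembly overlap {ov} <= {min_overlap_frac} x {smaller} "
                f"between {src1} and {src2} near position {s2}"
            )


def inject_misjoin(
    assembly: list[Contig], truth: TruthTable, seed: int = 0
) -> tuple[list[Contig], TruthTable]:
    """Fuse two non-adjacent clean contigs of one assembly into a chimera.

    The two contigs are removed and replaced by their concatenation,
    tagged ``chimera`` in the truth table.  The junction juxtaposes two
    genome loci that are not adjacent in truth.  Only interior contigs
    are fused: a junction falling on a genome extremity has no flanking
    sequence in any assembly, so no contig can diverge there and the
    misjoin would be unevidenced by construction.
    """
    source = assembly[0].source
    rng = np.random.default_rng(seed)
    entries = truth.for_source(source)
    clean_ids = [e.id for e in entries[1:-1] if e.tag == "clean"]
    order = {e.id: i for i, e in enumerate(entries)}
    candidates = [
        (a, b)
        for ai, a in enumerate(clean_ids)
        for b in clean_ids[ai + 1 :]
        if abs(order[a] - order[b]) >= 2
    ]
    if not candidates:
        raise ValueError("no two non-adjacent clean contigs to fuse")
    a_id, b_id = candidates[int(rng.integers(len(candidates)))]
    a = next(c for c in assembly if c.id == a_id)
    b = next(c for c in assembly if c.id == b_id)
    ea, eb = truth.lookup(source, a_id), truth.lookup(source, b_id)
    chimera_id = f"{a_id}x{b_id}"
    chimera = Contig(id=chimera_id, seq=a.seq + b.seq, source=source)
    new_assembly = [c for c in assembly if c.id not in (a_id, b_id)] + [chimera]
    new_entries = [
        e for e in truth.entries if not (e.source == source and e.id in (a_id, b_id))
    ]
    new_entries.append(
        TruthEntry(
            source=source,
            id=chimera_id,
            intervals=(ea.intervals[0], eb.intervals[0]),
            strands=(ea.strands[0], eb.strands[0]),
            tag="chimera",
        )
    )
    return new_assembly, TruthTable(genome_len=truth.genome_len, entries=new_entries)


def inject_insertion(
    assembly: list[Contig],
    truth: TruthTable,
    insert_len: int = 1000,
    seed: int = 0,
) -> tuple[list[Contig], TruthTable]:
    """Splice a novel sequence into the interior of one clean contig.

    The insertion point lies in the middle half of the contig, so both
    flanks remain substantial.  The inserted sequence shares no 20-mer
    with the genome.
    """
    source = assembly[0].source
    rng = np.random.default_rng(seed)
    clean = [
        e
        for e in truth.for_source(source)
        if e.tag == "clean" and e.intervals[0][1] - e.intervals[0][0] >= 4 * insert_len
    ]
    if not clean:
        raise ValueError("no clean contig long enough to host the insertion")
    entry = clean[int(rng.integers(len(clean)))]
    target = next(c for c in assembly if c.id == entry.id)
    offset = int(rng.integers(target.length // 4, 3 * target.length // 4))
    insert = _novel_vs_sources(assembly, insert_len, seed=int(rng.integers(2**31 - 1)))
    corrupted = Contig(
        id=target.id, seq=target.seq[:offset] + insert + target.seq[offset:],
        source=source,
    )
    new_assembly = [corrupted if c.id == target.id else c for c in assembly]
    new_entries = []
    for e in truth.entries:
        if e.source == source and e.id == entry.id:
            new_entries.append(
                replace(e, tag="insertion", insert_offset=offset, insert_len=insert_len)
            )
        else:
            new_entries.append(e)
    table = TruthTable(genome_len=truth.genome_len, entries=new_entries)
    table.insert_seq = insert  # type: ignore[attr-defined]
    return new_assembly, table


def _novel_vs_sources(assembly: list[Contig], length: int, seed: int) -> str:
    """Novel sequence sharing no 20-mer with any assembly contig.

    The assembly tiles the genome completely, so avoiding its contigs'
    k-mers avoids the genome's."""
    k = 20
    kmers: set[str] = set()
    for c in assembly:
        for i in range(c.length - k + 1):
            kmers.add(c.seq[i : i + k])
        rc = revcomp(c.seq)
        for i in range(c.length - k + 1):
            kmers.add(rc[i : i + k])
    rng = np.random.default_rng(seed)
    for _ in range(100):
        cand = "".join(rng.choice(_BASES, size=length))
        if all(cand[i : i + k] not in kmers for i in range(length - k + 1)):
            return cand
    raise RuntimeError("could not sample a novel insertion sequence")


def chimera_junction_window(
    assemblies: Mapping[str, Sequence[Contig]], truth: TruthTable, width: int = 100
) -> str:
    """Sequence window straddling the planted chimera's junction."""
    entry = next(e for e in truth.entries if e.tag == "chimera")
    contig = next(c for c in assemblies[entry.source] if c.id == entry.id)
    j = entry.intervals[0][1] - entry.intervals[0][0]
    return contig.seq[j - width : j + width]


def insert_sequence(
    assemblies: Mapping[str, Sequence[Contig]], truth: TruthTable
) -> str:
    """The novel sequence planted by :func:`inject_insertion`."""
    entry = next(e for e in truth.entries if e.tag == "insertion")
    contig = next(c for c in assemblies[entry.source] if c.id == entry.id)
    return contig.seq[entry.insert_offset : entry.insert_offset + entry.insert_len]


# ---------------------------------------------------------------------------
# Canned layouts
# ---------------------------------------------------------------------------


def standard_fixture(
    seed: int,
    genome_len: int = 60000,
    n_assemblies: int = 3,
    mean_len: int = 8000,
    min_overlap_frac: float = 0.35,
    gc: float = 0.5,
    chimera: bool = False,
    insertion: bool = False,
    insert_len: int = 1000,
) -> tuple[str, dict[str, list[Contig]], TruthTable]:
    """The canonical test genome: error-free staggered tilings, with
    optional planted corruption in the first assembly."""
    genome = simulate_genome(genome_len, gc=gc, seed=seed)
    assemblies, truth = fragment_into_assemblies(
        genome, n_assemblies, mean_len, min_overlap_frac, seed=seed + 1
    )
    labels = sorted(assemblies)
    if chimera:
        assemblies[labels[0]], truth = inject_misjoin(
            assemblies[labels[0]], truth, seed=seed + 2
        )
    if insertion:
        label = labels[1] if chimera else labels[0]
        assemblies[label], truth = inject_insertion(
            assemblies[label], truth, insert_len=insert_len, seed=seed + 3
        )
    return genome, assemblies, truth


def repeat_fixture(
    seed: int,
    genome_len: int = 24000,
    repeat_len: int = 2000,
    flank: int = 300,
) -> tuple[str, dict[str, list[Contig]], TruthTable, tuple[int, int]]:
    """Genome with a dispersed repeat at two loci, tiled so that the only
    way to join across each repeat locus is through the repeat itself.

    One contig carries each repeat copy in full with modest unique
    flanks, and the assemblies' breakpoints otherwise fall inside or
    near the repeat copies, keeping every unique cross-repeat overlap
    shorter than the repeat.  Returns (genome, assemblies, truth,
    (locus1, locus2)).
    """
    rng = np.random.default_rng(seed)
    locus1 = genome_len // 6
    locus2 = genome_len * 4 // 6
    genome = simulate_genome(genome_len, seed=seed)
    genome, _unit = plant_repeat(genome, repeat_len, [locus1, locus2], seed=seed + 1)

    j1 = int(rng.integers(repeat_len // 4, 3 * repeat_len // 4))
    j2 = int(rng.integers(repeat_len // 4, 3 * repeat_len // 4))
    mid = (locus1 + locus2 + repeat_len) // 2
    breakpoints = {
        # asm1 carries copy 1 in full: breaks just past each copy's flank
        "asm1": [locus1 + repeat_len + flank, locus2 + j2],
        # asm2 carries copy 2 in full
        "asm2": [locus1 + j1, locus2 - flank, ],
        # asm3 breaks inside both copies and in the unique middle
        "asm3": [locus1 + repeat_len // 2, mid, locus2 + repeat_len // 2],
    }
    assemblies, truth = assemblies_from_breakpoints(
        genome, breakpoints, seed=seed + 2
    )
    return genome, assemblies, truth, (locus1, locus2)
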