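# Methods

## Problem setting and model

`asmblend` treats assembly reconciliation as an evidence-weighing
problem over contig sets produced by independent assemblers from the
same bacterial genome. The working assumptions are: (i) every input
contig is mostly correct locally, so high-identity alignment between
contigs of different assemblies indicates shared genomic origin; (ii)
assemblers err mostly independently, so a junction or an inserted
segment present in exactly one assembly is suspect; (iii) the genome is
haploid and unphased, so reverse-complement orientation is arbitrary
per contig. No read data is used — all signal comes from contig-contig
alignment.

## Coordinate and alignment conventions

All intervals are 0-based half-open; strand is a flag, with `'-'`
meaning the query interval matches the reverse complement of the target
interval. External dialects (show-coords, BLAST outfmt 6; 1-based
inclusive, reversed endpoints for minus hits) are normalized at the
parser boundary. Identity is matched columns over all alignment columns
including gaps; an `N` never counts as a match anywhere in the engine.

### Built-in aligner

The default engine enumerates all maximal exact matches (MEMs) of at
least `min_mem` = 20 bp via a k-mer position index with
left-maximality filtering, against the forward and reverse-complement
target. Co-linear MEMs chain greedily (gap ≤ `max_gap` = 90 bp per
side, diagonal drift ≤ `band` = 50 bp); the best-coverage chain is
extracted repeatedly so genuinely distinct shared blocks become
separate records. Chains in consistent order separated by at most
`join_gap` = 600 bp are then joined when the bridging alignment of the
gap segments scores positive under the engine scoring (match +1,
mismatch −1, gap −2) — a cluster-then-join design; without it,
substitution noise near 5% fragments single local alignments, because
the expected spacing between 20 bp exact runs exceeds 90 bp. Gap
segments are closed with edlib global alignment (match counts derived
from the CIGAR), and ends are extended by a greedy ungapped walk under
the same scoring, stopping at the running-score maximum. The engine is
deterministic; ties break on (strand `+`, smaller `q_start`).

The greedy ungapped flank extension is exact for substitution-only
divergence and an approximation when indels fall in the extension zone;
the test suite bounds the discrepancy against a full Smith–Waterman
oracle (±5 bp per endpoint, ±0.005 identity) on pairs with up to 5%
substitution noise.

External backends (`nucmer`, `blastn`) are invoked with default
settings and parsed through the same normalization; a missing
executable raises an error directing the user to the builtin engine.
One engine serves all four phases by default.

## Integration thresholds

| Parameter | Default | Meaning |
|---|---|---|
| `contain_rate` / `contain_identity` | 0.95 / 0.95 | removal of contigs mostly within a representative |
| `extend_rate` / `extend_identity` | 0.80 / 0.95 | end-extension qualification |
| `merge_frac` | 0.30 | phase-3 overlap fraction of the smaller contig |
| `min_contig_len` | 100 bp | input filter and minimum surviving fragment |
| `end_window` | 100 bp | "reaches the end" tolerance; also breakpoint tolerance |
| `min_repeat_evidence_len` | 50 bp | minimum multi-mapped interval; phase-4 floor when R = 0 |

Every threshold is a strict `>`: a 300 bp overlap against a 30% × 1000 bp
requirement is rejected, 301 bp is accepted. Containment uses the
per-target alignment rate (the union of a contig's aligned intervals
*within one representative*), since containment is meaningful only
inside a single sequence.

Design choices where the procedure was genuinely open:

- **Extension requires a single qualifying record.** The extending
  alignment itself must cover > 80% of the extender and reach the
  representative's end. Requiring only the *total* aligned fraction
  lets a mostly-contained contig attach by a short secondary block that
  echoes a repeat copy elsewhere — observed to fuse repeat flanks in
  the repeat fixture — and lets corruption ride in: an interior
  insertion splits a contig's alignment into blocks each well under
  80%, so corrupted contigs never qualify under the per-record rule.
- **Extension repeats until closure,** one extender per end per round,
  with containment re-checked between rounds.
- **Misjoin evidence is two-sided.** Two contigs of one assembly must
  abut (± `end_window`) at an internal representative position with
  each diverging ≥ `end_window` past the junction, and must not
  themselves overlap end-to-end across it. One-sided divergence is not
  enough: a contig whose alignment stops at a repeat-copy boundary
  produces that signature on a perfectly clean representative. A
  flagged representative is replaced by the evidencing pair
  (supplemental representatives), then containment is re-run.
- **Uncertain-region coverage excludes only each position's supplier.**
  Coverage evidence for a representative position may come from any
  input contig except the one that contributed that very base (known
  from provenance). Excluding the whole provenance set instead can
  mark a legitimately extended representative's middle as uncovered
  once its neighbours were absorbed as extenders.
- **Merging is greedy longest-overlap-first with full realignment**
  after each merge (alignments are content-cached, so only pairs
  involving fresh sequence are recomputed), which makes bridging
  reachable and the procedure deterministic. The overlap copy is taken
  from the longer contig.
- **Repeat evidence is collected from the converged phase-3 state.**
  During early rounds, ordinary staggered overlaps still multi-cover
  intervals; after merging has fused genuine adjacencies, a query
  interval overlapped (≥ `min_repeat_evidence_len`) by two records to
  distinct regions indicates a repeat. The full record interval is
  promoted as evidence, not the pairwise intersection: when contig ends
  fall *inside* a repeat copy, intersections are truncated by the
  in-copy offset and systematically underestimate R, while the
  copy-to-copy record spans the planted length (measured 2000–2011 bp
  for a 2000 bp planted repeat).
- **Phase 4 requires overlap > R**, with floor
  `min_repeat_evidence_len` when no evidence was seen — merging on
  arbitrarily short exact overlaps is spurious-join-prone.

## Synthetic fixtures: what they emulate and what they do not

`fixtures` simulates an i.i.d. genome at a chosen GC, fragments it into
complete error-free tilings whose per-assembly breakpoints are phase
offset (offsets (i + ½)/n of the mean fragment, ± 5% jitter) so that
truth-adjacent cross-assembly fragments overlap by > 35% of the smaller
— the generator verifies this contract and raises otherwise. Strands
are random per contig. Corruption operators: a chimera fusing two
non-adjacent *interior* clean contigs (a junction on a genome extremity
has no flanking sequence anywhere, so no assembly could evidence it); an
insertion of novel sequence (sharing no 20-mer with the genome) in the
middle half of a contig; a dispersed repeat planted at two loci, with a
dedicated layout placing one full-copy carrier per locus and breakpoints
inside the copies so the only cross-repeat overlaps are the repeat
itself.

Deliberately not emulated: per-base sequencing error inside fragments
(kept error-free so algorithmic properties are exact; the aligner's
noise tolerance is exercised separately on noisy planted-overlap pairs),
coverage fluctuation, collapsed tandem repeats, and assembler-specific
artifact spectra. Passing tests therefore certify the integration
logic under the independence assumptions above, not performance on real
draft assemblies with correlated errors.

Problem sizes used by the test suite and acceptance script: the clean
reconstruction runs on 60 kb genomes with mean 8 kb fragments; the
seeded screening batteries (chimera, insertion, repeat) use 24 kb
genomes with mean 4 kb fragments, which exhibit the same geometry per
junction while keeping a 50-seed battery fast.

## Evaluation metrics

N50 is the largest L with contigs ≥ L summing to at least half the
assembly. %missed / %extra use an identity floor of 0.95 (the floor is
exposed; the convention in the literature is tool-dependent).
Intact-CDS counting requires the best contig hit to cover > 99% of the
CDS at > 99% identity, each CDS counted once. Error counting aligns
each contig to the reference with the chain gap ceiling lowered to 4 bp
so any indel ≥ 5 bp splits the alignment into adjacent co-linear
blocks; block adjacencies are then classified — opposite strands:
inversion; displaced or re-ordered by > 1 kb (per contig): relocation;
otherwise an unbalanced gap ≥ 5 bp: indel. A wholly reverse-complemented
contig has uniform strand and counts as no error. `split_at_ns`
partitions contigs at runs of more than 10 Ns before evaluation when an
upstream tool pads joins with uncalled bases.

## Degenerate inputs and numerical notes

Empty FASTA files parse to empty contig sets; integration requires ≥ 2
non-empty assemblies (error) and warns below 3. Contigs shorter than
`min_contig_len` are dropped on input. Identity comparisons happen on
exact fractions from integer match/column counts; no floating-point
tolerance is applied at thresholds, so "strictly greater" is
well-defined. All randomness lives in the fixture generator and is
fully seeded; the integrator itself is seed-free, and repeated runs are
byte-identical.

## Known limitations

- Alignment-rate unions ignore identity heterogeneity across records of
  one pair (records below the phase's floor are excluded wholesale).
- The repeat estimator sees only repeats expressed as multi-mapped
  intervals among surviving contigs; a repeat fully merged away in
  phase 3 leaves no evidence (R = 0), and phase 4 then falls back to a
  50 bp floor.
- Misjoin screening needs the junction loci covered with ≥ 100 bp of
  divergent flank by some single assembly; misjoins at genome termini
  or inside unassembled regions are undetectable in principle.
- The engine targets bacterial-scale drafts (tens of Mb total); it is
  quadratic in contig count per merge round, mitigated by content
  caching, and not intended for mammalian-scale inputs.
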