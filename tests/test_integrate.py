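"""Four-phase integration: unit behaviour of each phase."""

from __future__ import annotations

import numpy as np
import pytest

from asmblend.align import AlignmentCache, align_sets
from asmblend.fixtures import simulate_genome, standard_fixture
from asmblend.formats import Contig, revcomp
from asmblend.integrate import (
    IntegrationConfig,
    Segment,
    WorkingContig,
    detect_misjoin,
    extend_representative,
    find_end_overlap,
    integrate,
    phase1_collapse,
    phase2_screen,
    phase3_iterative_merge,
    phase4_merge,
    pick_representative,
)

from conftest import random_dna

CFG = IntegrationConfig()


def wc(source: str, cid: str, seq: str) -> WorkingContig:
    return WorkingContig(
        id=f"{source}|{cid}", seq=seq, segments=(Segment(source, cid, 0, len(seq)),)
    )


class TestPickRepresentative:
    def test_longest_wins(self, rng):
        pool = [
            wc("a", "c1", random_dna(rng, 100)),
            wc("a", "c2", random_dna(rng, 200)),
            wc("a", "c3", random_dna(rng, 150)),
        ]
        assert pick_representative(pool).id == "a|c2"

    def test_tie_break_lexicographic(self, rng):
        seq1, seq2 = random_dna(rng, 200), random_dna(rng, 200)
        pool = [wc("a2", "c1", seq1), wc("a1", "c2", seq2)]
        assert pick_representative(pool).id == "a1|c2"

    def test_singleton(self, rng):
        c = wc("a", "c1", random_dna(rng, 50))
        assert pick_representative([c]) is c

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pick_representative([])


class TestWorkingContig:
    def test_provenance_partitions_sequence(self, rng):
        c = wc("a", "c1", random_dna(rng, 120))
        with pytest.raises(ValueError):
            WorkingContig(id="x", seq=c.seq, segments=(Segment("a", "c1", 0, 60),))

    def test_slice_and_rc_track_source_coordinates(self, rng):
        seq = random_dna(rng, 100)
        c = wc("a", "c1", seq)
        piece = c.slice(20, 70)
        assert piece.seq == seq[20:70]
        assert piece.segments == (Segment("a", "c1", 20, 70, "+"),)
        flipped = piece.reverse_complement()
        assert flipped.seq == revcomp(seq[20:70])
        assert flipped.segments == (Segment("a", "c1", 20, 70, "-"),)


class TestPhase1:
    def test_three_identical_assemblies_collapse_to_one(self, rng):
        seq = random_dna(rng, 2000)
        pool = [wc(f"a{i}", "c1", seq) for i in range(1, 4)]
        reps = phase1_collapse(pool, CFG)
        assert len(reps) == 1
        assert reps.contigs[0].seq == seq

    def test_disjoint_contigs_both_retained(self, rng):
        pool = [wc("a", "c1", random_dna(rng, 1500)),
                wc("b", "c1", random_dna(rng, 1200))]
        reps = phase1_collapse(pool, CFG)
        assert len(reps) == 2

    def test_clean_tilings_map_to_genome_at_identity_one(self):
        genome, assemblies, _ = standard_fixture(
            seed=21, genome_len=20000, mean_len=4000)
        pool = [wc(src, c.id, c.seq) for src in assemblies for c in assemblies[src]]
        reps = phase1_collapse(pool, CFG)
        assert len(reps) <= len(pool)
        for rep in reps:
            assert rep.seq in genome or revcomp(rep.seq) in genome
        # the count bound belongs to the full pipeline, whose merging
        # phases absorb the staggered chain
        res = integrate(assemblies)
        assert len(res.contigs) <= min(len(v) for v in assemblies.values())


class TestExtendRepresentative:
    def _setup(self, rng, rep_seq, cand_seqs):
        rep = wc("r", "rep", rep_seq)
        pool = [wc("p", f"e{i}", s) for i, s in enumerate(cand_seqs, 1)]
        table = align_sets(pool, [rep], CFG.align, AlignmentCache())
        return rep, pool, table

    def test_fully_interior_candidate_never_extends(self, rng):
        genome = random_dna(rng, 12000)
        rep, pool, table = self._setup(rng, genome[:10000], [genome[4000:9000]])
        assert extend_representative(rep, pool, table, CFG).seq == genome[:10000]

    def test_exact_concatenation_on_right_end(self, rng):
        # extender is >80% aligned to the rep and overhangs by 300 bp
        genome = random_dna(rng, 15000)
        rep, pool, table = self._setup(rng, genome[:10000], [genome[8500:10300]])
        ext = extend_representative(rep, pool, table, CFG)
        assert ext.seq == genome[:10300]

    def test_mostly_unaligned_candidate_never_extends(self, rng):
        # candidate reaches the end but only 29% of it aligns: below the
        # 80% rule, so it must be left to the overlap-merging phases
        genome = random_dna(rng, 15000)
        rep, pool, table = self._setup(rng, genome[:10000], [genome[8000:15000]])
        assert extend_representative(rep, pool, table, CFG).seq == genome[:10000]

    def test_reverse_complement_extender(self, rng):
        genome = random_dna(rng, 15000)
        rep, pool, table = self._setup(
            rng, genome[:10000], [revcomp(genome[8500:10300])])
        ext = extend_representative(rep, pool, table, CFG)
        assert ext.seq == genome[:10300]

    def test_longest_overhang_wins(self, rng):
        genome = random_dna(rng, 17000)
        rep, pool, table = self._setup(
            rng, genome[:10000], [genome[8000:10300], genome[8200:10400]])
        ext = extend_representative(rep, pool, table, CFG)
        assert ext.seq == genome[:10400]


class TestDetectMisjoin:
    def test_rep_matching_all_assemblies_is_clean(self, rng):
        seq = random_dna(rng, 3000)
        rep = wc("a1", "c1", seq)
        inputs = [rep] + [wc(f"a{i}", "c1", seq) for i in (2, 3)]
        cache = AlignmentCache()
        table = align_sets(inputs, [rep], CFG.align, cache)
        assert detect_misjoin(rep, inputs, table, CFG, cache) == []

    def test_planted_chimera_flagged_near_breakpoint(self, rng):
        genome = random_dna(rng, 50000)
        rep = wc("a1", "chim", genome[:5000] + genome[40000:45000])
        inputs = [
            rep,
            wc("a2", "c1", genome[2000:9000]),
            wc("a2", "c2", genome[38000:44000]),
        ]
        cache = AlignmentCache()
        table = align_sets(inputs, [rep], CFG.align, cache)
        evidence = detect_misjoin(rep, inputs, table, CFG, cache)
        assert evidence
        assert abs(evidence[0].breakpoint - 5000) <= CFG.end_window
        assert {evidence[0].left_contig, evidence[0].right_contig} == {
            "a2|c1", "a2|c2"}

    def test_genuine_overlap_corroborates_junction(self, rng):
        genome = random_dna(rng, 20000)
        rep = wc("a1", "c1", genome[:12000])
        inputs = [
            rep,
            wc("a2", "c1", genome[:7000]),
            wc("a2", "c2", genome[5000:12000]),  # shares 2 kb with c1
        ]
        cache = AlignmentCache()
        table = align_sets(inputs, [rep], CFG.align, cache)
        assert detect_misjoin(rep, inputs, table, CFG, cache) == []


class TestPhase2:
    def test_fully_tiled_reps_pass_unchanged(self, rng):
        genome = random_dna(rng, 10000)
        rep = wc("a1", "c1", genome)
        inputs = [rep, wc("a2", "c1", genome[:6000]), wc("a2", "c2", genome[5000:])]
        from asmblend.integrate import RepresentativeSet

        out = phase2_screen(RepresentativeSet([rep]), inputs, CFG)
        assert [c.seq for c in out.contigs] == [genome]

    def test_planted_insertion_splits_rep(self, rng):
        genome = random_dna(rng, 10000)
        insert = random_dna(rng, 1000)
        corrupted = genome[:5000] + insert + genome[5000:]
        rep = wc("a1", "c1", corrupted)
        inputs = [rep, wc("a2", "c1", genome[:6000]), wc("a2", "c2", genome[4500:])]
        from asmblend.integrate import RepresentativeSet

        out = phase2_screen(RepresentativeSet([rep]), inputs, CFG)
        seqs = sorted(c.seq for c in out.contigs)
        assert sorted([genome[:5000], genome[5000:]]) == seqs

    def test_uncovered_tail_clipped(self, rng):
        genome = random_dna(rng, 8000)
        tail = random_dna(rng, 200)
        rep = wc("a1", "c1", genome + tail)
        inputs = [rep, wc("a2", "c1", genome[:5000]), wc("a2", "c2", genome[4000:])]
        from asmblend.integrate import RepresentativeSet

        out = phase2_screen(RepresentativeSet([rep]), inputs, CFG)
        assert [c.seq for c in out.contigs] == [genome]


class TestFindEndOverlap:
    def _candidate(self, rng, ov, flip=False, min_frac=0.30):
        genome = random_dna(rng, 3000)
        a = wc("x", "a", genome[:1000])
        bseq = genome[1000 - ov : 3000]
        b = wc("x", "b", revcomp(bseq) if flip else bseq)
        table = align_sets([a, b], [a, b], CFG.align, AlignmentCache())
        return find_end_overlap(a, b, table, CFG, min_frac * 1000)

    def test_overlap_exactly_at_threshold_rejected(self, rng):
        assert self._candidate(rng, 300) is None

    def test_overlap_just_above_threshold_accepted(self, rng):
        cand = self._candidate(rng, 301)
        assert cand is not None
        assert cand.overlap_len == 301
        assert cand.merged_len == 3000 - 1 + 1 - 0  # 1000 + 2301 - 301
        assert cand.orientation == "+"

    def test_reverse_complement_candidate(self, rng):
        cand = self._candidate(rng, 400, flip=True)
        assert cand is not None
        assert cand.orientation == "-"
        assert cand.overlap_len == 400


class TestPhase34:
    def test_two_contigs_with_forty_percent_overlap_merge(self, rng):
        genome = random_dna(rng, 1600)
        contigs = [wc("a", "c1", genome[:1000]), wc("b", "c1", genome[600:1600])]
        merged, repeat = phase3_iterative_merge(contigs, CFG)
        assert len(merged) == 1
        assert merged[0].seq == genome
        assert repeat.max_repeat_len == 0

    def test_bridging_contig_joins_three(self, rng):
        genome = random_dna(rng, 3000)
        contigs = [
            wc("a", "c1", genome[:1200]),
            wc("b", "c1", genome[700:2300]),
            wc("c", "c1", genome[1800:3000]),
        ]
        merged, _ = phase3_iterative_merge(contigs, CFG)
        assert len(merged) == 1 and merged[0].seq == genome

    def test_phase4_gated_by_repeat_estimate(self, rng):
        from asmblend.integrate import RepeatEstimate

        genome = random_dna(rng, 3500)
        make = lambda ov: [
            wc("a", "c1", genome[: 1500 + ov]),
            wc("b", "c1", genome[1500 : 3500]),
        ]
        merged = phase4_merge(make(500), RepeatEstimate(300), CFG)
        assert len(merged) == 1 and merged[0].seq == genome
        not_merged = phase4_merge(make(250), RepeatEstimate(300), CFG)
        assert len(not_merged) == 2

    def test_provenance_partitions_merged_output(self, rng):
        genome = random_dna(rng, 1600)
        contigs = [wc("a", "c1", genome[:1000]), wc("b", "c1", genome[600:1600])]
        merged, _ = phase3_iterative_merge(contigs, CFG)
        segs = merged[0].segments
        assert sum(s.end - s.start for s in segs) == 1600
        assert {s.source for s in segs} == {"a", "b"}


class TestIntegrate:
    def test_three_identical_single_contig_assemblies(self, rng):
        seq = random_dna(rng, 2000)
        res = integrate(
            {f"a{i}": [Contig(id="c1", seq=seq, source=f"a{i}")] for i in (1, 2, 3)}
        )
        assert len(res.contigs) == 1
        assert res.contigs[0].seq in (seq, revcomp(seq))

    def test_fewer_than_two_assemblies_rejected(self, rng):
        with pytest.raises(ValueError):
            integrate({"a": [Contig(id="c", seq=random_dna(rng, 500), source="a")]})

    def test_two_assemblies_warns(self, rng, caplog):
        seq = random_dna(rng, 2000)
        with caplog.at_level("WARNING", logger="asmblend"):
            integrate({f"a{i}": [Contig(id="c1", seq=seq, source=f"a{i}")]
                       for i in (1, 2)})
        assert any("at least 3" in m for m in caplog.messages)

    def test_short_contigs_dropped_on_input(self, rng):
        seq = random_dna(rng, 2000)
        short = Contig(id="tiny", seq=random_dna(rng, 50), source="a1")
        res = integrate({
            "a1": [Contig(id="c1", seq=seq, source="a1"), short],
            "a2": [Contig(id="c1", seq=seq, source="a2")],
            "a3": [Contig(id="c1", seq=seq, source="a3")],
        })
        assert len(res.contigs) == 1

    def test_corrupted_fixture_still_reconstructs_cleanly(self):
        genome, assemblies, truth = standard_fixture(
            seed=42, chimera=True, insertion=True)
        res = integrate(assemblies)
        assert len(res.contigs) <= 3
        for c in res.contigs:
            assert c.seq in genome or revcomp(c.seq) in genome
        # junction and insert are gone (checked in depth in acceptance tests)
        ch = next(e for e in truth.entries if e.tag == "chimera")
        chimera = next(
            c for c in assemblies[ch.source] if c.id == ch.id)
        j = ch.intervals[0][1] - ch.intervals[0][0]
        win = chimera.seq[j - 80 : j + 80]
        assert not any(win in c.seq or win in revcomp(c.seq) for c in res.contigs)

    def test_report_counts_and_provenance(self, small_clean_fixture):
        genome, assemblies, _ = small_clean_fixture
        res = integrate(assemblies)
        rep = res.report
        assert rep["n_assemblies"] == 3
        assert set(rep["phases"]) == {"phase1", "phase2", "phase3", "phase4"}
        assert rep["output_contigs"] == len(res.contigs)
        for cid, segs in rep["provenance"].items():
            length = next(c.length for c in res.contigs if c.id == cid)
            assert sum(s["end"] - s["start"] for s in segs) == length
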