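"""Built-in MEM seed-and-extend aligner."""

from __future__ import annotations

import numpy as np
import pytest

from asmblend.align import (
    AlignConfig,
    align_pair,
    align_sets,
    alignment_rate,
    chain_and_extend,
    find_mems,
)
from asmblend.formats import AlignmentRecord, AlignmentTable, Contig, revcomp

from _oracles import brute_mems, sw_local
from conftest import mutate, random_dna


class TestFindMems:
    def test_identity_contains_full_length_match(self, rng):
        a = random_dna(rng, 100)
        mems = find_mems(a, a, 20)
        assert (0, 0, 100, "+") in [tuple(m) for m in mems]

    def test_disjoint_sequences_empty(self):
        a, b = "A" * 50, "C" * 50
        assert find_mems(a, b, 8) == []

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            find_mems("ACGTACGT", "ACGTACGT", 7)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)
        # plant a shared block, some of it reverse-complemented
        block = random_dna(rng, 60)
        a = a[:100] + block + a[160:]
        b = b[:40] + block + b[100:180] + revcomp(block) + b[240:]
        got = {tuple(m) for m in find_mems(a, b, 12)}
        assert got == brute_mems(a, b, 12)

    def test_n_never_matches(self):
        a = "ACGTACGTNACGTACGT" * 2
        got = {tuple(m) for m in find_mems(a, a, 8)}
        assert got == brute_mems(a, a, 8)
        for qs, ts, L, strand in got:
            assert "N" not in a[qs : qs + L]


class TestChainAndExtend:
    def test_single_full_length_anchor(self, rng):
        a = random_dna(rng, 150)
        recs = chain_and_extend(find_mems(a, a, 20), a, a)
        (r,) = recs
        assert (r.q_start, r.q_end, r.t_start, r.t_end) == (0, 150, 0, 150)
        assert r.identity == 1.0 and r.strand == "+"

    def test_one_mismatch_identity_arithmetic(self, rng):
        a = random_dna(rng, 201)
        b = a[:100] + ("A" if a[100] != "A" else "C") + a[101:]
        recs = chain_and_extend(find_mems(a, b, 20), a, b)
        (r,) = recs
        assert r.identity == pytest.approx(200 / 201)
        assert (r.q_start, r.q_end) == (0, 201)

    @pytest.mark.parametrize("noise", [0.0, 0.02])
    def test_planted_overlap_identity_tracks_substitution_rate(self, noise):
        """Reported identity within +-0.005 of the planted rate over 20 pairs."""
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(20):
            core = random_dna(rng, 800)
            a = random_dna(rng, 1200) + core
            b = mutate(rng, core, noise) + random_dna(rng, 1200)
            recs = align_pair(Contig(id="a", seq=a), Contig(id="b", seq=b))
            best = max(recs, key=lambda r: r.identity * r.aln_len)
            errs.append(abs(best.identity - (1 - noise)))
        assert np.mean(errs) < 0.005

    def test_two_separate_blocks_give_two_records(self, rng):
        b1, b2 = random_dna(rng, 150), random_dna(rng, 150)
        a = b1 + random_dna(rng, 500) + b2
        b = b2 + random_dna(rng, 500) + b1  # order swapped: not co-linear
        recs = align_pair(Contig(id="a", seq=a), Contig(id="b", seq=b))
        spans = sorted((r.q_start, r.q_end) for r in recs)
        assert len(recs) == 2
        assert spans[0][1] <= 160 and spans[1][0] >= 640


class TestAlignPairProperties:
    def test_symmetry_under_transposition(self, rng):
        core = random_dna(rng, 400)
        a = random_dna(rng, 300) + core
        b = core + random_dna(rng, 300)
        ca, cb = Contig(id="a", seq=a), Contig(id="b", seq=b)
        fwd = align_pair(ca, cb)
        rev = align_pair(cb, ca)
        assert {(r.q_start, r.q_end, r.t_start, r.t_end, r.strand) for r in fwd} == {
            (r.t_start, r.t_end, r.q_start, r.q_end, r.strand) for r in rev
        }

    def test_reverse_complement_invariance(self, rng):
        core = random_dna(rng, 400)
        a = random_dna(rng, 200) + core
        b = core + random_dna(rng, 200)
        ca = Contig(id="a", seq=a)
        plus = align_pair(ca, Contig(id="b", seq=b))
        minus = align_pair(ca, Contig(id="b", seq=revcomp(b)))
        n = len(b)
        flipped = {
            (r.q_start, r.q_end, n - r.t_end, n - r.t_start,
             "-" if r.strand == "+" else "+")
            for r in plus
        }
        assert {
            (r.q_start, r.q_end, r.t_start, r.t_end, r.strand) for r in minus
        } == flipped

    def test_determinism(self, rng):
        a = Contig(id="a", seq=random_dna(rng, 1500))
        b = Contig(id="b", seq=a.seq[700:] + random_dna(rng, 700))
        assert align_pair(a, b) == align_pair(a, b)

    def test_engine_interval_matches_dp_oracle(self):
        """On a noisy planted overlap the engine's interval and identity
        agree with full Smith-Waterman."""
        rng = np.random.default_rng(1234)
        core = random_dna(rng, 700)
        a = random_dna(rng, 900) + core
        b = mutate(rng, core, 0.03) + random_dna(rng, 900)
        recs = align_pair(Contig(id="a", seq=a), Contig(id="b", seq=b))
        best = max(recs, key=lambda r: r.identity * r.aln_len)
        _, q0, q1, t0, t1, oid = sw_local(a, b)
        assert abs(best.q_start - q0) <= 5 and abs(best.q_end - q1) <= 5
        assert abs(best.t_start - t0) <= 5 and abs(best.t_end - t1) <= 5
        assert best.identity == pytest.approx(oid, abs=0.005)


class TestAlignSets:
    def test_distinct_copies_align_full_length(self, rng):
        seq = random_dna(rng, 500)
        t = align_sets(
            [Contig(id="c1", seq=seq)], [Contig(id="c2", seq=seq)]
        )
        (r,) = t.records
        assert (r.q_start, r.q_end, r.identity) == (0, 500, 1.0)

    def test_self_pairs_skipped(self, rng):
        cs = [Contig(id=f"c{i}", seq=random_dna(rng, 300)) for i in range(3)]
        t = align_sets(cs, cs)
        assert all(r.query_id != r.target_id for r in t.records)
        assert len(t.records) == 0  # disjoint random contigs share no MEM

    def test_unknown_backend(self, rng):
        cs = [Contig(id="c", seq=random_dna(rng, 100))]
        with pytest.raises(ValueError):
            align_sets(cs, [Contig(id="d", seq=random_dna(rng, 100))],
                       AlignConfig(backend="bwa"))

    def test_missing_executable_mentions_builtin(self, rng, monkeypatch):
        monkeypatch.setenv("PATH", "")
        cs = [Contig(id="c", seq=random_dna(rng, 100))]
        with pytest.raises(RuntimeError, match="builtin"):
            align_sets(cs, [Contig(id="d", seq=random_dna(rng, 100))],
                       AlignConfig(backend="nucmer"))


@pytest.mark.skipif(
    __import__("shutil").which("blastn") is None, reason="blastn not on PATH"
)
class TestBlastBackend:
    def test_builtin_and_blastn_agree_on_planted_overlap(self, rng):
        core = random_dna(rng, 900)
        a = Contig(id="a", seq=random_dna(rng, 1100) + core)
        b = Contig(id="b", seq=core + random_dna(rng, 1100))
        builtin = align_sets([a], [b]).records
        blast = align_sets([a], [b], AlignConfig(backend="blastn")).records
        rb = max(builtin, key=lambda r: r.q_span)
        rx = max(blast, key=lambda r: r.q_span)
        assert abs(rb.q_start - rx.q_start) <= 5
        assert abs(rb.q_end - rx.q_end) <= 5
        assert rx.identity == pytest.approx(rb.identity, abs=0.005)


class TestAlignmentRate:
    def _table(self, intervals, qlen=100):
        recs = [
            AlignmentRecord("q", "t", s, e, s, e, "+", 1.0, e - s)
            for s, e in intervals
        ]
        return AlignmentTable(recs, {"q": qlen}, {"t": 1000})

    def test_full_cover(self):
        assert alignment_rate(self._table([(0, 100)]), "q") == 1.0

    def test_interval_union(self):
        assert alignment_rate(self._table([(0, 50), (25, 75)]), "q") == 0.75

    def test_no_records(self):
        t = AlignmentTable([], {"q": 100}, {"t": 100})
        assert alignment_rate(t, "q") == 0.0

    def test_per_target_restriction(self):
        recs = [
            AlignmentRecord("q", "t1", 0, 50, 0, 50, "+", 1.0, 50),
            AlignmentRecord("q", "t2", 50, 100, 0, 50, "+", 1.0, 50),
        ]
        t = AlignmentTable(recs, {"q": 100}, {"t1": 100, "t2": 100})
        assert alignment_rate(t, "q") == 1.0
        assert alignment_rate(t, "q", "t1") == 0.5

    def test_unknown_query(self):
        with pytest.raises(KeyError):
            alignment_rate(self._table([(0, 10)]), "zz")
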