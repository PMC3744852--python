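import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clippair import (
    AlignedRead,
    OverlapMatch,
    ReferenceStore,
    SimCnv,
    classify_read,
    compute_breakpoints,
    find_overlap,
    pair_reads,
    refine_breakpoints,
)
from clippair.cigar import parse_cigar
from clippair.simulate import engineer_homology, generate_reference, simulate_junction_reads

from _oracle import best_overlap
from conftest import random_dna


def make_read(seq, clip_class, clip_len, pos=1, rname="sim1", name="r",
              cigar=None):
    match_len = len(seq) - clip_len
    if cigar is None:
        cigar = (f"{match_len}M{clip_len}S" if clip_class == "MS"
                 else f"{clip_len}S{match_len}M")
    return AlignedRead(
        name=name, rname=rname, pos=pos, cigar=parse_cigar(cigar), seq=seq,
        clip_class=clip_class, clip_len=clip_len, match_len=match_len,
        ref_span=match_len,
    )


class TestFindOverlap:
    def test_exact_fifty_base_overlap(self):
        core = random_dna(150, seed=1)
        ms = make_read(core[:100], "MS", 20, name="ms")
        sm = make_read(core[50:150], "SM", 20, name="sm")
        match = find_overlap(ms, sm, min_overlap=28, max_mismatch_frac=0.08)
        assert match is not None
        assert (match.common_len, match.mismatches) == (50, 0)
        assert match.common_string == core[50:100]

    def test_short_overlap_is_rejected(self):
        # only admissible overlap has 27 bases, one below the minimum
        core = random_dna(173, seed=2)
        ms = make_read(core[:100], "MS", 13, name="ms")
        sm = make_read(core[73:173], "SM", 13, name="sm")
        assert find_overlap(ms, sm, min_overlap=28) is None
        assert find_overlap(ms, sm, min_overlap=27) is not None

    def test_mismatch_budget_is_floor_of_fraction(self):
        core = list(random_dna(150, seed=3))
        ms = make_read("".join(core[:100]), "MS", 20, name="ms")
        sm_seq = list("".join(core[50:150]))
        # 5 mismatches in a 50-base overlap: 5 > floor(0.08*50) = 4
        for i in (3, 13, 23, 33, 43):
            sm_seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sm_seq[i]]
        sm = make_read("".join(sm_seq), "SM", 20, name="sm")
        assert find_overlap(ms, sm) is None
        # 4 mismatches are tolerated
        sm_seq = list("".join(core[50:150]))
        for i in (3, 13, 23, 33):
            sm_seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sm_seq[i]]
        match = find_overlap(ms, make_read("".join(sm_seq), "SM", 20))
        assert match is not None and match.mismatches == 4

    def test_common_string_must_contain_both_clips(self):
        core = random_dna(130, seed=4)
        ms = make_read(core[:100], "MS", 40, name="ms")
        sm = make_read(core[70:130], "SM", 40, name="sm")
        # true overlap is 30 < s1 + s2 = 80
        assert find_overlap(ms, sm, min_overlap=28) is None

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        cl_true=st.integers(28, 80),
        n_mut=st.integers(0, 5),
    )
    def test_agrees_with_exhaustive_oracle(self, seed, cl_true, n_mut):
        rng = np.random.default_rng(seed)
        core = random_dna(200 - cl_true, seed + 1)
        s1 = int(rng.integers(11, min(cl_true, 45)))
        s2 = cl_true - s1 if cl_true - s1 >= 11 else 11
        ms_seq = core[:100]
        sm_seq = list(core[100 - cl_true : 200 - cl_true])
        for pos in rng.choice(100, size=n_mut, replace=False):
            sm_seq[pos] = "ACGT"[(("ACGT".index(sm_seq[pos])) + 1) % 4]
        sm_seq = "".join(sm_seq)
        ms = make_read(ms_seq, "MS", s1)
        sm = make_read(sm_seq, "SM", s2)
        got = find_overlap(ms, sm, min_overlap=28, max_mismatch_frac=0.08)
        expected = best_overlap(ms_seq, sm_seq, s1, s2, 28, 0.08)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert (got.common_len, got.mismatches) == (expected[0], expected[1])


class TestComputeBreakpoints:
    def test_deletion_arithmetic(self):
        ms = make_read("A" * 100, "MS", 30, pos=101)
        sm = make_read("A" * 100, "SM", 35, pos=500)
        match = OverlapMatch(ms, sm, common_len=70, mismatches=0,
                             common_string="A" * 70)
        assert compute_breakpoints(match) == (170, 500, 5)

    def test_duplication_arithmetic(self):
        ms = make_read("A" * 100, "MS", 40, pos=201)
        sm = make_read("A" * 100, "SM", 48, pos=90)
        match = OverlapMatch(ms, sm, common_len=88, mismatches=0,
                             common_string="A" * 88)
        a, b, dx = compute_breakpoints(match)
        assert (a, b, dx) == (260, 90, 0)
        assert a > b  # tandem duplication by the sign rule

    def test_toy_deletion_round_trip(self):
        # implant a tiny deletion and rebuild both junction reads by hand
        cnv = SimCnv("sim1", 20, 31, "DEL", 0)
        store = engineer_homology(generate_reference(60, seed=9), cnv)
        recs = simulate_junction_reads(store, cnv, read_length=16, n=0,
                                       x_values=[11, 5])
        reads = [classify_read(r, min_clip=3) for r in recs]
        ms = next(r for r in reads if r.clip_class == "MS")
        sm = next(r for r in reads if r.clip_class == "SM")
        variant = store.fetch("sim1", 1, 20) + store.fetch("sim1", 31, 60)
        assert ms.seq in variant and sm.seq in variant
        match = find_overlap(ms, sm, min_overlap=5)
        assert compute_breakpoints(match)[:2] == (20, 31)


def _junction_match(store, cnv, x_ms=75, x_sm=30, min_clip=11):
    recs = simulate_junction_reads(store, cnv, read_length=100, n=0,
                                   x_values=[x_ms, x_sm])
    reads = [classify_read(r, min_clip=min_clip) for r in recs]
    ms = next(r for r in reads if r.clip_class == "MS")
    sm = next(r for r in reads if r.clip_class == "SM")
    return find_overlap(ms, sm)


class TestRefineBreakpoints:
    def test_no_homology_unique_minimum(self):
        cnv = SimCnv("sim1", 600, 1100, "DEL", 0)
        store = engineer_homology(generate_reference(2000, seed=11), cnv)
        match = _junction_match(store, cnv)
        a, b, dx = compute_breakpoints(match)
        assert refine_breakpoints(a, b, dx, match, store) == (600, 1100, 0)

    def test_three_base_homology_full_shift_set(self, del_with_homology):
        store, cnv = del_with_homology
        match = _junction_match(store, cnv)
        a_raw, b_raw, dx_raw = compute_breakpoints(match)
        assert dx_raw == 3  # aligner absorbed the repeat into the SM match
        assert refine_breakpoints(a_raw, b_raw, dx_raw, match, store) == (600, 1100, 3)

    def test_read_error_matches_enumeration_oracle(self, del_with_homology):
        from _oracle import refine as oracle_refine

        store, cnv = del_with_homology
        match = _junction_match(store, cnv)
        a_raw, b_raw, dx_raw = compute_breakpoints(match)
        # corrupt one base inside the repeat part of the common string
        s2 = match.read_sm.clip_len
        cs = list(match.common_string)
        cs[s2 + 1] = "ACGT"[("ACGT".index(cs[s2 + 1]) + 1) % 4]
        match.common_string = "".join(cs)
        got = refine_breakpoints(a_raw, b_raw, dx_raw, match, store)
        expected = oracle_refine(
            match.common_string, a_raw, b_raw, dx_raw, s2,
            match.common_len, store.sequence("sim1"),
        )
        assert got == expected

    def test_out_of_bounds_window_discards_call(self, del_with_homology):
        store, cnv = del_with_homology
        match = _junction_match(store, cnv)
        a_raw, b_raw, dx_raw = compute_breakpoints(match)
        tiny = ReferenceStore({"sim1": store.sequence("sim1")[:1100]})
        assert refine_breakpoints(a_raw, b_raw, dx_raw, match, tiny) is None


class TestPairReads:
    def test_far_apart_reads_are_never_tested(self, small_ref):
        ms = make_read(random_dna(100, 1), "MS", 30, pos=1000)
        sm = make_read(random_dna(100, 2), "SM", 30, pos=3_001_001)
        stats = {}
        drafts = pair_reads([ms], [sm], search_window=2_000_000, ref=small_ref,
                            stats=stats)
        assert drafts == [] and stats["pairs_tested"] == 0

    def test_empty_sm_batch(self, small_ref):
        ms = make_read(random_dna(100, 1), "MS", 30, pos=1000)
        assert pair_reads([ms], [], 2_000_000, ref=small_ref) == []

    def test_one_pair_one_draft(self, del_with_homology):
        store, cnv = del_with_homology
        recs = simulate_junction_reads(store, cnv, read_length=100, n=0,
                                       x_values=[75, 30])
        reads = [classify_read(r, 11) for r in recs]
        ms = [r for r in reads if r.clip_class == "MS"]
        sm = [r for r in reads if r.clip_class == "SM"]
        drafts = pair_reads(ms, sm, 2_000_000, ref=store)
        assert len(drafts) == 1
        assert (drafts[0].a, drafts[0].b, drafts[0].dx) == (600, 1100, 3)


class TestCallInvariants:
    def test_reconstruction_identical_for_every_shift(self, del_with_homology):
        store, cnv = del_with_homology
        recs = simulate_junction_reads(store, cnv, read_length=100, n=0,
                                       x_values=[75, 30])
        reads = [classify_read(r, 11) for r in recs]
        ms = [r for r in reads if r.clip_class == "MS"]
        sm = [r for r in reads if r.clip_class == "SM"]
        call = pair_reads(ms, sm, 2_000_000, ref=store)[0]
        k = 100
        # fixed window, split moved to each equivalent pair (a+d, b+d)
        rebuilt = {
            store.fetch("sim1", call.a - k + 1, call.a + d)
            + store.fetch("sim1", call.b + d, call.b + k - 1)
            for d in range(call.dx + 1)
        }
        assert len(rebuilt) == 1  # every split yields the same junction string

    def test_reported_pair_is_leftmost(self, del_with_homology):
        store, cnv = del_with_homology
        recs = simulate_junction_reads(store, cnv, read_length=100, n=0,
                                       x_values=[75, 30])
        reads = [classify_read(r, 11) for r in recs]
        call = pair_reads(
            [r for r in reads if r.clip_class == "MS"],
            [r for r in reads if r.clip_class == "SM"],
            2_000_000, ref=store,
        )[0]
        k = 50
        at = lambda a, b: (store.fetch("sim1", a - k + 1, a)
                           + store.fetch("sim1", b, b + k - 1))
        assert at(call.a - 1, call.b - 1) != at(call.a, call.b)
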