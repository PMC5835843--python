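"""IsomiR calling: candidate enumeration, resolution, labels, oracle agreement."""

import numpy as np
import pytest

from isomirseq.bruteforce import BruteForceCaller
from isomirseq.caller import (
    CallerParams,
    IsomiRCaller,
    call_collapsed,
    call_reads,
    enumerate_candidates,
    isomir_label,
    resolve,
)
from isomirseq.reference import build_reference

from conftest import MIR16_5P

PARAMS = CallerParams()


def single(read, ref, params=PARAMS):
    return resolve(enumerate_candidates(read, ref, params))


class TestEnumerateAndResolve:
    def test_canonical_identity(self, mir16_ref):
        call = single(MIR16_5P, mir16_ref)
        assert call.mature_id == "toy-miR-16-5p"
        assert (call.offset5, call.offset3, call.mismatches) == (0, 0, 0)
        assert call.is_canonical and not call.ambiguous
        assert call.label == "0"

    def test_three_prime_trim(self, mir16_ref):
        call = single(MIR16_5P[:-1], mir16_ref)
        assert (call.offset5, call.offset3) == (0, -1)
        assert call.label == "-1"

    def test_templated_three_prime_addition(self, mir16_ref):
        flank = mir16_ref.templated_flank("toy-miR-16-5p", "3prime", 1)
        call = single(MIR16_5P + flank, mir16_ref)
        assert (call.offset5, call.offset3) == (0, 1)
        assert call.templated3 and call.nt_tail == ""
        assert call.label == "+1"

    def test_non_templated_tail(self, mir16_ref):
        flank = mir16_ref.templated_flank("toy-miR-16-5p", "3prime", 1)
        tail = {"A": "C"}.get(flank, "A")
        call = single(MIR16_5P + tail, mir16_ref)
        assert (call.offset5, call.offset3) == (0, 1)
        assert not call.templated3 and call.nt_tail == tail
        assert call.mismatches == 0
        assert call.label == f"nt:{tail}"

    def test_five_prime_templated_extension(self, mir16_ref):
        ext = mir16_ref.templated_flank("toy-miR-16-5p", "5prime", 1)
        call = single(ext + MIR16_5P[:-1], mir16_ref)
        assert (call.offset5, call.offset3) == (1, -1)
        assert call.label == "5p:+1"

    def test_five_prime_trim_label(self, mir16_ref):
        call = single(MIR16_5P[1:], mir16_ref)
        assert call.offset5 == -1
        assert call.label == "5p:-1"

    def test_single_mismatch_tolerated_and_labelled(self, mir16_ref):
        mutated = "C" + MIR16_5P[1:] if MIR16_5P[0] != "C" else "A" + MIR16_5P[1:]
        call = single(mutated, mir16_ref)
        assert (call.offset5, call.offset3, call.mismatches) == (0, 0, 1)
        assert not call.is_canonical
        assert call.label == "0|m1"

    def test_outside_window_unassigned(self, mir16_ref):
        assert single(MIR16_5P[:-4], mir16_ref) is None  # 4-nt trim
        assert single("ACGT" * 6, mir16_ref) is None

    def test_perfect_match_beats_mismatch(self, mir16_ref):
        # exact canonical of the 3p arm, not a 1-mismatch variant of 5p
        canonical_3p = mir16_ref.canonical("toy-miR-16-3p")
        call = single(canonical_3p, mir16_ref)
        assert call.mature_id == "toy-miR-16-3p"
        assert call.mismatches == 0

    def test_duplicated_mature_is_ambiguous(self):
        hp = "GGCAC" + MIR16_5P + "TTTGAGGTCCAGG"
        ref = build_reference(
            {"h1": hp, "h2": hp},
            [("dupA-5p", "h1", "5p", 5, 27), ("dupB-5p", "h2", "5p", 5, 27)],
        )
        call = resolve(enumerate_candidates(MIR16_5P, ref, PARAMS))
        assert call.ambiguous


class TestWindowExhaustiveness:
    """Every in-window construction is assigned; every outside one is not."""

    @pytest.mark.parametrize("offset5", range(-3, 4))
    @pytest.mark.parametrize("offset3", range(-3, 4))
    def test_all_window_offsets_recovered(self, toy_ref, offset5, offset3):
        hp, mat = toy_ref.mature("toy-miR-2-5p")
        start, end = mat.start - offset5, mat.end + offset3
        read = hp.sequence[start:end]
        call = single(read, toy_ref)
        assert call is not None
        assert call.mature_id == "toy-miR-2-5p"
        assert (call.offset5, call.offset3) == (offset5, offset3)
        assert call.mismatches == 0

    def test_four_nt_trim_unassigned(self, toy_ref):
        seq = toy_ref.canonical("toy-miR-2-5p")
        assert single(seq[:-4], toy_ref) is None


class TestLabels:
    @pytest.mark.parametrize(
        "fields,expected",
        [
            ((0, 0, True, "", 0), "0"),
            ((0, -3, True, "", 0), "-3"),
            ((0, 2, True, "", 0), "+2"),
            ((1, 0, True, "", 0), "5p:+1"),
            ((-2, -1, True, "", 0), "5p:-2"),
            ((0, 1, False, "T", 0), "nt:T"),
            ((0, 0, True, "", 1), "0|m1"),
        ],
    )
    def test_label_mapping(self, fields, expected):
        from isomirseq.caller import Candidate

        off5, off3, templ, tail, mm = fields
        assert isomir_label(Candidate("x", off5, off3, templ, tail, mm)) == expected


class TestCallStreams:
    def test_uniform_stream_all_canonical(self, mir16_ref):
        reads = [(f"r{i}", MIR16_5P) for i in range(100)]
        calls, summary = call_reads(reads, mir16_ref)
        assert summary.assigned == summary.total_reads == 100
        assert all(c.is_canonical for c in calls)

    def test_empty_stream(self, mir16_ref):
        calls, summary = call_reads([], mir16_ref)
        assert calls == [] and summary.total_reads == 0

    def test_alphabet_violation_unassigned(self, mir16_ref):
        _, summary = call_reads([("r0", "ACGTN" + MIR16_5P[5:])], mir16_ref)
        assert summary.unassigned == 1

    def test_collapsed_matches_streamed(self, mir16_ref):
        variants = [MIR16_5P, MIR16_5P[:-1], MIR16_5P[:-3]]
        stream = [(f"r{i}", v) for i, v in enumerate(variants * 5)]
        calls, s1 = call_reads(stream, mir16_ref)
        collapsed = {v: 5 for v in variants}
        counts, s2 = call_collapsed(collapsed, mir16_ref)
        assert s1.as_dict() == s2.as_dict()
        from collections import Counter

        streamed = Counter((c.mature_id, c.label) for c in calls)
        assert dict(streamed) == counts

    def test_determinism(self, toy_ref):
        rng = np.random.default_rng(5)
        reads = [
            ("r%d" % i, "".join(rng.choice(list("ACGT"), 22))) for i in range(200)
        ]
        c1, _ = call_reads(reads, toy_ref)
        c2, _ = call_reads(reads, toy_ref)
        assert c1 == c2


def _random_read(rng, ref, params):
    """Random reads biased toward the interesting window boundary."""
    kind = rng.integers(0, 5)
    mature_ids = ref.mature_ids()
    mid = mature_ids[rng.integers(len(mature_ids))]
    hp, mat = ref.mature(mid)
    if kind == 0:  # pure random
        return "".join(rng.choice(list("ACGT"), rng.integers(15, 30)))
    offset5 = int(rng.integers(-4, 5))
    offset3 = int(rng.integers(-4, 5))
    start, end = mat.start - offset5, mat.end + offset3
    if start < 0 or end > len(hp.sequence) or end - start < 1:
        return "".join(rng.choice(list("ACGT"), rng.integers(15, 30)))
    read = hp.sequence[start:end]
    if kind == 2:  # substitutions (possibly beyond tolerance)
        n_mut = int(rng.integers(1, 3))
        chars = list(read)
        for p in rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False):
            chars[p] = "ACGT".replace(chars[p], "")[rng.integers(3)]
        read = "".join(chars)
    elif kind == 3:  # non-templated tail
        t = int(rng.integers(1, 4))
        read = read + "".join(rng.choice(list("ACGT"), t))
    return read


class TestOracleEquivalence:
    """The anchored enumerator agrees with the literal string-table oracle."""

    def test_agreement_on_random_reads(self, toy_ref):
        oracle = BruteForceCaller(toy_ref, PARAMS)
        caller = IsomiRCaller(toy_ref, PARAMS)
        rng = np.random.default_rng(42)
        for _ in range(300):
            read = _random_read(rng, toy_ref, PARAMS)
            mine = caller.call(read)
            ref_call = oracle.call(read)
            if mine is None or ref_call is None:
                assert mine is None and ref_call is None, read
            else:
                assert (
                    mine.mature_id,
                    mine.offset5,
                    mine.offset3,
                    mine.templated3,
                    mine.nt_tail,
                    mine.mismatches,
                    mine.ambiguous,
                ) == (
                    ref_call.mature_id,
                    ref_call.offset5,
                    ref_call.offset3,
                    ref_call.templated3,
                    ref_call.nt_tail,
                    ref_call.mismatches,
                    ref_call.ambiguous,
                ), read

    def test_candidate_sets_agree_on_variants(self, mir16_ref):
        oracle = BruteForceCaller(mir16_ref, PARAMS)
        for read in [
            MIR16_5P,
            MIR16_5P[:-2],
            MIR16_5P + "A",
            MIR16_5P[2:] + "TT",
        ]:
            mine = set(enumerate_candidates(read, mir16_ref, PARAMS))
            theirs = set(oracle.candidates(read))
            assert mine == theirs, read
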