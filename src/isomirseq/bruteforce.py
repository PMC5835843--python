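"""Exhaustive reference caller for validation.

This module answers the same question as :mod:`isomirseq.caller` — which
isomiR class explains a read — by the most literal possible route: it
materialises *every* variant string in the tolerance window (all 5'/3'
offsets, every possible non-templated tail over {A,C,G,T}) for every
mature, and string-compares the read against each one.  It shares no code
path with the anchored enumerator, so agreement between the two on random
reads is a meaningful check.  It is far too slow for real libraries and
exists only for toy references.
"""

from __future__ import annotations

from itertools import product
from typing import NamedTuple

from .caller import Candidate, CallerParams, IsomiRCall
from .reference import ReferenceSet

__all__ = ["BruteForceCaller", "enumerate_variant_strings"]

_ALPHABET = "ACGT"


class _Variant(NamedTuple):
    string: str
    body_len: int  # region where substitutions are tolerated; tail must match exactly
    candidate: Candidate


def enumerate_variant_strings(
    ref: ReferenceSet, params: CallerParams
) -> list[_Variant]:
    """Every error-free variant string in the window, with its class.

    Templated variants are hairpin slices; tailed variants are a hairpin
    slice ending at or beyond the canonical 3' end plus every possible
    tail of length 1..max_add3 (tails equal to the templated continuation
    are skipped — those strings *are* the templated variants).
    """
    variants: list[_Variant] = []
    for hp, mat in ref.iter_matures():
        seq = hp.sequence
        for offset5 in range(-params.max_trim5, params.max_add5 + 1):
            s = mat.start - offset5
            if s < 0:
                continue
            for offset3 in range(-params.max_trim3, params.max_add3 + 1):
                end = mat.end + offset3
                # fully templated slice
                if s < end <= len(seq):
                    string = seq[s:end]
                    variants.append(
                        _Variant(
                            string,
                            len(string),
                            Candidate(mat.mature_id, offset5, offset3, True, "", 0),
                        )
                    )
                # tailed: body [s, body_end) with body_end >= canonical end,
                # plus every non-templated tail completing the offset
                if offset3 < 1:
                    continue
                for t in range(1, offset3 + 1):
                    body_end = end - t
                    if body_end < mat.end or body_end > len(seq):
                        continue
                    body = seq[s:body_end]
                    if not body:
                        continue
                    flank = seq[body_end : body_end + t]
                    for tail_tuple in product(_ALPHABET, repeat=t):
                        tail = "".join(tail_tuple)
                        if tail == flank:
                            continue
                        variants.append(
                            _Variant(
                                body + tail,
                                len(body),
                                Candidate(
                                    mat.mature_id, offset5, offset3, False, tail, 0
                                ),
                            )
                        )
    return variants


def _score(c: Candidate) -> tuple:
    # same scoring definition as the production resolver, restated here
    return (
        c.mismatches,
        abs(c.offset5) + abs(c.offset3),
        0 if c.templated3 else 1,
        len(c.nt_tail),
    )


class BruteForceCaller:
    """Literal string-table caller for toy references."""

    def __init__(self, ref: ReferenceSet, params: CallerParams | None = None):
        self.params = params or CallerParams()
        self.variants = enumerate_variant_strings(ref, self.params)

    def candidates(self, read: str) -> list[Candidate]:
        found: dict[Candidate, None] = {}
        limit = self.params.max_mismatch
        for var in self.variants:
            if len(var.string) != len(read):
                continue
            # tail region must match exactly; substitutions only in the body
            if read[var.body_len :] != var.string[var.body_len :]:
                continue
            mm = sum(
                a != b
                for a, b in zip(read[: var.body_len], var.string[: var.body_len])
            )
            if mm > limit:
                continue
            cand = var.candidate._replace(mismatches=mm)
            found.setdefault(cand, None)
        return list(found)

    def call(self, read: str) -> IsomiRCall | None:
        cands = self.candidates(read)
        if not cands:
            return None
        best = min(
            cands,
            key=lambda c: _score(c)
            + (c.mature_id, c.offset5, c.offset3, c.nt_tail),
        )
        ambiguous = any(
            _score(c) == _score(best) and c.mature_id != best.mature_id
            for c in cands
        )
        return IsomiRCall(
            read_id=None,
            mature_id=best.mature_id,
            offset5=best.offset5,
            offset3=best.offset3,
            templated3=best.templated3,
            nt_tail=best.nt_tail,
            mismatches=best.mismatches,
            ambiguous=ambiguous,
        )
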