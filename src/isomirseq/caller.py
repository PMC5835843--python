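"""Assignment of clean reads to mature miRNAs and isomiR classes.

A read is explained as a *variant* of an annotated mature: the 5' end may
be trimmed or (templated) extended by up to a few nucleotides, the 3' end
trimmed or extended, and the body may carry a small number of
substitutions.  A 3' extension is *templated* when it matches the hairpin
flank downstream of the mature end; otherwise the extra nucleotides are a
*non-templated tail* (e.g. post-processing uridylation).  Tails are
counted as an addition event, never as mismatches, and are only accepted
as pure extensions (the tail starts at or beyond the canonical 3' end).

Sign convention for offsets (matching the usual isomiR nomenclature):
negative = trimming, positive = addition, on either end.  The canonical
read is (0, 0) with zero mismatches and no tail, labelled ``"0"``.

Candidate enumeration walks every mature and every 5' offset in the
window, anchors the read on the hairpin, and scores the alignment; the
best candidate wins by (fewest mismatches, smallest total end offset,
templated over tailed, shortest tail).  Ties across different matures are
flagged ambiguous and dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .preprocess import ReadRecord
from .reference import ReferenceSet

__all__ = [
    "CallerParams",
    "Candidate",
    "IsomiRCall",
    "CallSummary",
    "IsomiRCaller",
    "enumerate_candidates",
    "resolve",
    "call_reads",
    "call_collapsed",
    "isomir_label",
    "parse_label",
    "label_sort_key",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class CallerParams:
    """Alignment tolerance window.

    Defaults mirror the common small-RNA mapper settings: one mismatch,
    up to 3 nt trimming on either end, up to 3 nt 3' addition.  5'
    additions are accepted only when templated (drawn from the hairpin).
    """

    max_mismatch: int = 1
    max_trim5: int = 3
    max_trim3: int = 3
    max_add3: int = 3
    max_add5: int = 3

    def __post_init__(self) -> None:
        for name in ("max_mismatch", "max_trim5", "max_trim3", "max_add3", "max_add5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class Candidate(NamedTuple):
    mature_id: str
    offset5: int
    offset3: int
    templated3: bool
    nt_tail: str
    mismatches: int


@dataclass(frozen=True)
class IsomiRCall:
    read_id: str | None
    mature_id: str
    offset5: int
    offset3: int
    templated3: bool
    nt_tail: str
    mismatches: int
    ambiguous: bool

    @property
    def is_canonical(self) -> bool:
        return (
            self.offset5 == 0
            and self.offset3 == 0
            and self.mismatches == 0
            and not self.nt_tail
        )

    @property
    def label(self) -> str:
        return isomir_label(self)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["label"] = self.label
        return d


@dataclass
class CallSummary:
    total_reads: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous_dropped: int = 0

    def check(self) -> None:
        if self.assigned + self.unassigned + self.ambiguous_dropped != self.total_reads:
            raise AssertionError("call summary does not partition reads")

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once > limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def enumerate_candidates(
    read: str, ref: ReferenceSet, params: CallerParams | None = None
) -> list[Candidate]:
    """All window-consistent explanations of ``read``; may be empty.

    For every mature and 5' offset the read is anchored on the hairpin at
    ``start - offset5``; the fully templated alignment and every tail
    split (tail length 1..max_add3, tail starting at or beyond the
    canonical end) are scored.  A tail split whose tail equals the
    templated flank is suppressed — it is the templated candidate.
    """
    params = params or CallerParams()
    read_len = len(read)
    if read_len < 1:
        raise ValueError("empty read")
    out: list[Candidate] = []
    for hp, mat in ref.iter_matures():
        seq = hp.sequence
        hp_len = len(seq)
        for offset5 in range(-params.max_trim5, params.max_add5 + 1):
            s = mat.start - offset5
            if s < 0:
                continue
            offset3 = s + read_len - mat.end
            if not (-params.max_trim3 <= offset3 <= params.max_add3):
                continue
            # fully templated alignment
            if s + read_len <= hp_len:
                mm = _mismatches(read, seq[s : s + read_len], params.max_mismatch)
                if mm <= params.max_mismatch:
                    out.append(
                        Candidate(mat.mature_id, offset5, offset3, True, "", mm)
                    )
            # tail splits: read = templated body + non-templated 3' tail
            max_t = min(params.max_add3, offset3, read_len - 1)
            for t in range(1, max_t + 1):
                body_len = read_len - t
                body_end = s + body_len
                if body_end < mat.end or body_end > hp_len:
                    continue
                tail = read[body_len:]
                flank = seq[body_end : body_end + t]
                if flank == tail:
                    continue  # identical to (part of) the templated candidate
                mm = _mismatches(read, seq[s:body_end], params.max_mismatch)
                if mm <= params.max_mismatch:
                    out.append(
                        Candidate(mat.mature_id, offset5, offset3, False, tail, mm)
                    )
    return out


def _score(c: Candidate) -> tuple:
    return (
        c.mismatches,
        abs(c.offset5) + abs(c.offset3),
        0 if c.templated3 else 1,
        len(c.nt_tail),
    )


def _tiebreak(c: Candidate) -> tuple:
    return (c.mature_id, c.offset5, c.offset3, c.nt_tail)


def resolve(
    candidates: Iterable[Candidate],
    read_id: str | None = None,
) -> IsomiRCall | None:
    """Pick the best candidate; flag cross-mature score ties as ambiguous."""
    cands = list(candidates)
    if not cands:
        return None
    best = min(cands, key=lambda c: _score(c) + _tiebreak(c))
    best_score = _score(best)
    ambiguous = any(
        _score(c) == best_score and c.mature_id != best.mature_id for c in cands
    )
    return IsomiRCall(
        read_id=read_id,
        mature_id=best.mature_id,
        offset5=best.offset5,
        offset3=best.offset3,
        templated3=best.templated3,
        nt_tail=best.nt_tail,
        mismatches=best.mismatches,
        ambiguous=ambiguous,
    )


def isomir_label(call: IsomiRCall | Candidate) -> str:
    """Compact isomiR class label.

    ``"0"`` for the exact canonical read; signed 3' offset (``"-2"``,
    ``"+1"``) for 3'-only variants; ``"5p:±k"`` for any variant of the 5'
    end (3' changes of such reads are not encoded — the one-axis label
    projection); ``"nt:<tail>"`` for non-templated tails.  Calls carrying
    substitutions get a ``"|m<k>"`` suffix so that ``"0"`` always means an
    exact canonical match.
    """
    if call.nt_tail:
        base = f"nt:{call.nt_tail}"
    elif call.offset5 != 0:
        base = f"5p:{call.offset5:+d}"
    elif call.offset3 != 0:
        base = f"{call.offset3:+d}"
    else:
        base = "0"
    if call.mismatches:
        base = f"{base}|m{call.mismatches}"
    return base


def parse_label(label: str) -> tuple[int, str, str]:
    """Sortable decomposition of a label: (class rank, payload, mm suffix)."""
    core, _, msuffix = label.partition("|")
    if core == "0":
        return (0, "", msuffix)
    if core.startswith("5p:"):
        return (2, core[3:], msuffix)
    if core.startswith("nt:"):
        return (3, core[3:], msuffix)
    return (1, core, msuffix)


def label_sort_key(label: str) -> tuple:
    rank, payload, msuffix = parse_label(label)
    if rank in (1, 2):
        num = int(payload) if rank == 1 else int(payload)
        return (bool(msuffix), rank, num, "", msuffix)
    return (bool(msuffix), rank, 0, payload, msuffix)


def is_templated_label(label: str) -> bool:
    """Templated classes only: excludes non-templated tails."""
    return parse_label(label)[0] != 3


class IsomiRCaller:
    """Memoising caller: identical read sequences are resolved once.

    Small-RNA libraries are massively redundant (a handful of isomiR
    sequences dominate), so per-unique-sequence memoisation makes calling
    linear in unique reads rather than total reads.
    """

    def __init__(self, ref: ReferenceSet, params: CallerParams | None = None):
        self.ref = ref
        self.params = params or CallerParams()
        self._memo: dict[str, IsomiRCall | None] = {}

    def call(self, bases: str) -> IsomiRCall | None:
        try:
            return self._memo[bases]
        except KeyError:
            pass
        if set(bases) - _DNA:
            result: IsomiRCall | None = None
        else:
            result = resolve(enumerate_candidates(bases, self.ref, self.params))
        self._memo[bases] = result
        return result


def call_reads(
    reads: Iterable[ReadRecord | tuple[str, str]],
    ref: ReferenceSet,
    params: CallerParams | None = None,
    drop_ambiguous: bool = True,
) -> tuple[list[IsomiRCall], CallSummary]:
    """Resolve a clean read stream; output order follows input order."""
    caller = IsomiRCaller(ref, params)
    summary = CallSummary()
    calls: list[IsomiRCall] = []
    for rec in reads:
        if isinstance(rec, ReadRecord):
            read_id, bases = rec.read_id, rec.bases
        else:
            read_id, bases = rec
        summary.total_reads += 1
        result = caller.call(bases)
        if result is None:
            summary.unassigned += 1
            continue
        if result.ambiguous and drop_ambiguous:
            summary.ambiguous_dropped += 1
            continue
        summary.assigned += 1
        calls.append(
            IsomiRCall(
                read_id=read_id,
                mature_id=result.mature_id,
                offset5=result.offset5,
                offset3=result.offset3,
                templated3=result.templated3,
                nt_tail=result.nt_tail,
                mismatches=result.mismatches,
                ambiguous=result.ambiguous,
            )
        )
    summary.check()
    return calls, summary


def call_collapsed(
    insert_counts: Mapping[str, int],
    ref: ReferenceSet,
    params: CallerParams | None = None,
    drop_ambiguous: bool = True,
    caller: IsomiRCaller | None = None,
) -> tuple[dict[tuple[str, str], int], CallSummary]:
    """Resolve collapsed inserts into ``(mature_id, label) -> count``."""
    caller = caller or IsomiRCaller(ref, params)
    summary = CallSummary()
    counts: dict[tuple[str, str], int] = {}
    for bases, n in insert_counts.items():
        summary.total_reads += n
        result = caller.call(bases)
        if result is None:
            summary.unassigned += n
            continue
        if result.ambiguous and drop_ambiguous:
            summary.ambiguous_dropped += n
            continue
        summary.assigned += n
        key = (result.mature_id, result.label)
        counts[key] = counts.get(key, 0) + n
    summary.check()
    return counts, summary


def write_calls_tsv(calls: Iterable[IsomiRCall], path: str | Path) -> None:
    cols = [
        "read_id",
        "mature_id",
        "offset5",
        "offset3",
        "templated3",
        "nt_tail",
        "mismatches",
        "label",
    ]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for c in calls:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.read_id,
                        c.mature_id,
                        c.offset5,
                        c.offset3,
                        int(c.templated3),
                        c.nt_tail,
                        c.mismatches,
                        c.label,
                    )
                )
                + "\n"
            )
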