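"""Read cleanup for 3'-adapter small-RNA libraries.

Libraries sequenced for more cycles than the insert length read through
into the 3' ligation adapter.  Cleanup therefore (in this fixed order):

1. drops reads failing the FASTX-style quality rule (at least
   ``quality_percent`` % of bases with Phred score >= ``quality_cutoff``,
   evaluated on the untrimmed read);
2. locates the adapter — an exact full-adapter match anywhere, or an exact
   adapter *prefix* of at least ``min_prefix`` nt running to the read's 3'
   end (the read ends mid-adapter) — and drops reads with no adapter, or
   consisting of adapter only;
3. trims at the adapter start and drops inserts shorter than
   ``min_length``.

Each read is assigned exactly one fate, so the report counts always
partition the input.  Quality strings are Sanger Phred+33; other encodings
are rejected, not guessed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "ReadRecord",
    "PreprocessParams",
    "PreprocessReport",
    "find_adapter",
    "quality_pass",
    "preprocess_read",
    "preprocess_reads",
    "preprocess_fastq",
    "preprocess_collapsed",
    "read_fastq",
]

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

_PHRED_OFFSET = 33
_MAX_PHRED = 93

FATES = ("kept", "quality", "no_adapter", "adapter_only", "short")


@dataclass(frozen=True)
class ReadRecord:
    """One small-RNA read: id, bases and Phred+33 quality string."""

    read_id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: bases/quals length mismatch "
                f"({len(self.bases)} vs {len(self.quals)})"
            )

    def phred(self) -> list[int]:
        return [ord(c) - _PHRED_OFFSET for c in self.quals]


@dataclass(frozen=True)
class PreprocessParams:
    adapter: str = DEFAULT_ADAPTER
    quality_percent: float = 90.0
    quality_cutoff: int = 30
    min_length: int = 15
    min_prefix: int = 5  # shortest adapter prefix accepted at the 3' end

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not (0 < self.quality_percent <= 100):
            raise ValueError("quality_percent must be in (0, 100]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_prefix < 1:
            raise ValueError("min_prefix must be >= 1")


@dataclass
class PreprocessReport:
    """Per-sample accounting; counts partition the input reads."""

    input_reads: int = 0
    kept_reads: int = 0
    dropped_quality: int = 0
    dropped_no_adapter: int = 0
    dropped_adapter_only: int = 0
    dropped_short: int = 0

    def record(self, fate: str, n: int = 1) -> None:
        self.input_reads += n
        if fate == "kept":
            self.kept_reads += n
        elif fate == "quality":
            self.dropped_quality += n
        elif fate == "no_adapter":
            self.dropped_no_adapter += n
        elif fate == "adapter_only":
            self.dropped_adapter_only += n
        elif fate == "short":
            self.dropped_short += n
        else:  # pragma: no cover
            raise ValueError(f"unknown fate {fate!r}")

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_quality
            + self.dropped_no_adapter
            + self.dropped_adapter_only
            + self.dropped_short
        )

    def check(self) -> None:
        if self.kept_reads + self.total_dropped != self.input_reads:
            raise AssertionError("preprocess report does not partition input")

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def find_adapter(bases: str, adapter: str, min_prefix: int = 5) -> int | None:
    """Position of the leftmost adapter occurrence, or ``None``.

    An occurrence is an exact match of the full adapter anywhere, or an
    exact match of an adapter prefix (>= ``min_prefix`` nt) that extends to
    the read's 3' end.  Position 0 means the read is adapter-only.
    """
    full = bases.find(adapter)
    candidates = [] if full < 0 else [full]
    # read may end inside the adapter: longest prefix wins (leftmost start)
    max_k = min(len(adapter) - 1, len(bases))
    for k in range(max_k, min_prefix - 1, -1):
        if bases.endswith(adapter[:k]):
            candidates.append(len(bases) - k)
            break
    if not candidates:
        return None
    return min(candidates)


def quality_pass(
    quals: str | Sequence[int], percent: float = 90.0, cutoff: int = 30
) -> bool:
    """FASTX ``fastq_quality_filter`` rule, boundary inclusive.

    True iff at least ``percent`` % of positions have Phred >= ``cutoff``.
    """
    if len(quals) == 0:
        raise ValueError("empty quality string")
    if isinstance(quals, str):
        scores = [ord(c) - _PHRED_OFFSET for c in quals]
    else:
        scores = list(quals)
    for s in scores:
        if not (0 <= s <= _MAX_PHRED):
            raise ValueError(f"Phred score {s} outside [0, {_MAX_PHRED}]; "
                             "expected Sanger +33 encoding")
    n_hi = sum(s >= cutoff for s in scores)
    return n_hi * 100 >= percent * len(scores)


def preprocess_read(
    bases: str, quals: str, params: PreprocessParams
) -> tuple[str, tuple[str, str] | None]:
    """Assign one read its fate; return ``(fate, trimmed)``.

    ``trimmed`` is the ``(bases, quals)`` insert when the fate is
    ``"kept"``, else ``None``.
    """
    if not quality_pass(quals, params.quality_percent, params.quality_cutoff):
        return "quality", None
    pos = find_adapter(bases, params.adapter, params.min_prefix)
    if pos is None:
        return "no_adapter", None
    if pos == 0:
        return "adapter_only", None
    if pos < params.min_length:
        return "short", None
    return "kept", (bases[:pos], quals[:pos])


def preprocess_reads(
    reads: Iterable[ReadRecord], params: PreprocessParams | None = None
) -> tuple[list[ReadRecord], PreprocessReport]:
    """Clean an in-memory read stream; order preserved."""
    params = params or PreprocessParams()
    report = PreprocessReport()
    kept: list[ReadRecord] = []
    for rec in reads:
        fate, trimmed = preprocess_read(rec.bases, rec.quals, params)
        report.record(fate)
        if trimmed is not None:
            kept.append(ReadRecord(rec.read_id, trimmed[0], trimmed[1]))
    report.check()
    return kept, report


def preprocess_collapsed(
    collapsed: Mapping[tuple[str, str], int] | Iterable[tuple[str, str, int]],
    params: PreprocessParams | None = None,
) -> tuple[dict[str, int], PreprocessReport]:
    """Clean collapsed reads (unique ``(bases, quals)`` with multiplicity).

    Collapsing identical reads is the standard small-RNA-seq speed trick:
    each unique read is processed once and its count carried along.
    Returns insert-sequence counts plus the report.
    """
    params = params or PreprocessParams()
    report = PreprocessReport()
    inserts: dict[str, int] = {}
    items = collapsed.items() if isinstance(collapsed, Mapping) else (
        ((b, q), n) for b, q, n in collapsed
    )
    for (bases, quals), n in items:
        fate, trimmed = preprocess_read(bases, quals, params)
        report.record(fate, n)
        if trimmed is not None:
            insert = trimmed[0]
            inserts[insert] = inserts.get(insert, 0) + n
    report.check()
    return inserts, report


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (optionally gzipped) as :class:`ReadRecord`."""
    with pysam.FastxFile(str(path)) as fh:
        for i, entry in enumerate(fh):
            if entry.quality is None:
                raise ValueError(f"{path}: record {i} ({entry.name}) has no quality")
            yield ReadRecord(entry.name, entry.sequence.upper(), entry.quality)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for rec in reads:
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{rec.quals}\n")


def preprocess_fastq(
    in_path: str | Path,
    params: PreprocessParams | None = None,
    out_path: str | Path | None = None,
    report_path: str | Path | None = None,
) -> tuple[list[ReadRecord], PreprocessReport]:
    """File-level convenience wrapper around :func:`preprocess_reads`."""
    kept, report = preprocess_reads(read_fastq(in_path), params)
    if out_path is not None:
        write_fastq(kept, out_path)
    if report_path is not None:
        report.to_json(report_path)
    return kept, report
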