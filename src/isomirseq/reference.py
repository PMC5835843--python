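"""Hairpin references and mature-miRNA annotations.

Mature miRNAs are annotated as intervals on their precursor hairpins.
The hairpin is the source of truth for two things downstream code needs:

* the *canonical* mature sequence (the annotated slice), and
* the *templated flanks* — hairpin nucleotides immediately adjacent to a
  mature end.  An end variant whose extra nucleotides match the flank is
  "templated" (consistent with a shifted Dicer cleavage site); anything
  else is a non-templated tail.

Coordinates are 0-based half-open internally.  GFF3 / TSV input and output
use the miRBase convention (1-based inclusive) and are converted at the
boundary.  Sequences are normalised to the DNA alphabet (U -> T, uppercase)
so that reads and references compare directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureAnnotation",
    "HairpinReference",
    "ReferenceSet",
    "load_hairpins",
    "load_mature_annotations",
    "load_mature_table",
    "build_reference",
    "write_reference",
]

_DNA = frozenset("ACGT")

ARMS = ("5p", "3p")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its hairpin (0-based half-open)."""

    mature_id: str
    arm: str
    start: int
    end: int
    canonical_sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for {self.mature_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HairpinReference:
    """A precursor hairpin with up to one mature annotation per arm."""

    hairpin_id: str
    sequence: str
    matures: list[MatureAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"hairpin {self.hairpin_id}: non-ACGT characters {sorted(bad)}"
            )
        arms_seen: set[str] = set()
        for mat in self.matures:
            if mat.end > len(self.sequence):
                raise ValueError(
                    f"mature {mat.mature_id} span [{mat.start}, {mat.end}) "
                    f"exceeds hairpin {self.hairpin_id} length {len(self.sequence)}"
                )
            if mat.arm in arms_seen:
                raise ValueError(
                    f"hairpin {self.hairpin_id}: more than one {mat.arm} mature"
                )
            arms_seen.add(mat.arm)
            expected = self.sequence[mat.start : mat.end]
            if mat.canonical_sequence != expected:
                raise ValueError(
                    f"mature {mat.mature_id}: canonical sequence does not match "
                    f"hairpin slice"
                )

    def mature_for_arm(self, arm: str) -> MatureAnnotation | None:
        for mat in self.matures:
            if mat.arm == arm:
                return mat
        return None


class ReferenceSet:
    """All hairpins plus an index from mature id to its hairpin and arm.

    Iteration order follows hairpin insertion order (FASTA record order),
    then 5p before 3p, so downstream tables are deterministic.
    """

    def __init__(self, hairpins: Mapping[str, HairpinReference]):
        self.hairpins: dict[str, HairpinReference] = dict(hairpins)
        self.mature_index: dict[str, tuple[str, str]] = {}
        for hp in self.hairpins.values():
            hp.validate()
            for mat in sorted(hp.matures, key=lambda m: ARMS.index(m.arm)):
                if mat.mature_id in self.mature_index:
                    raise ValueError(f"duplicate mature id {mat.mature_id!r}")
                self.mature_index[mat.mature_id] = (hp.hairpin_id, mat.arm)

    def __len__(self) -> int:
        return len(self.hairpins)

    def mature(self, mature_id: str) -> tuple[HairpinReference, MatureAnnotation]:
        try:
            hairpin_id, arm = self.mature_index[mature_id]
        except KeyError:
            raise KeyError(f"unknown mature id {mature_id!r}") from None
        hp = self.hairpins[hairpin_id]
        mat = hp.mature_for_arm(arm)
        assert mat is not None
        return hp, mat

    def canonical(self, mature_id: str) -> str:
        return self.mature(mature_id)[1].canonical_sequence

    def iter_matures(self) -> Iterator[tuple[HairpinReference, MatureAnnotation]]:
        for hp in self.hairpins.values():
            for arm in ARMS:
                mat = hp.mature_for_arm(arm)
                if mat is not None:
                    yield hp, mat

    def mature_ids(self) -> list[str]:
        return [mat.mature_id for _, mat in self.iter_matures()]

    def hairpins_with_both_arms(self) -> list[str]:
        return [
            hp.hairpin_id
            for hp in self.hairpins.values()
            if hp.mature_for_arm("5p") is not None
            and hp.mature_for_arm("3p") is not None
        ]

    def templated_flank(self, mature_id: str, side: str, k: int) -> str:
        """Up to ``k`` hairpin nucleotides adjacent to a mature end.

        ``side`` is ``"5prime"`` (upstream of the mature start, returned in
        hairpin orientation) or ``"3prime"`` (downstream of the mature end).
        Shorter than ``k`` when the hairpin terminates.
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        hp, mat = self.mature(mature_id)
        if side == "3prime":
            return hp.sequence[mat.end : mat.end + k]
        if side == "5prime":
            return hp.sequence[max(0, mat.start - k) : mat.start]
        raise ValueError(f"side must be '5prime' or '3prime', got {side!r}")


def load_hairpins(fasta_path: str | Path) -> dict[str, str]:
    """Read hairpin precursors from FASTA, normalised to uppercase DNA.

    Record order is preserved.  Duplicate ids, empty files and non-nucleotide
    characters are errors.
    """
    fasta_path = Path(fasta_path)
    hairpins: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in hairpins:
            raise ValueError(f"duplicate hairpin id {record.id!r} in {fasta_path}")
        seq = normalize_sequence(str(record.seq))
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"hairpin {record.id!r}: invalid characters {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"hairpin {record.id!r}: empty sequence")
        hairpins[record.id] = seq
    if not hairpins:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return hairpins


def _infer_arm(mature_id: str, start: int, end: int, hairpin_len: int) -> str:
    lowered = mature_id.lower()
    if lowered.endswith("-5p"):
        return "5p"
    if lowered.endswith("-3p"):
        return "3p"
    midpoint = (start + end) / 2
    return "5p" if midpoint < hairpin_len / 2 else "3p"


def build_reference(
    hairpins: Mapping[str, str],
    annotations: Iterable[tuple[str, str, str | None, int, int]],
) -> ReferenceSet:
    """Assemble a :class:`ReferenceSet`.

    ``annotations`` are tuples ``(mature_id, hairpin_id, arm_or_None,
    start, end)`` in internal 0-based half-open coordinates.  A ``None``
    arm is inferred from the id suffix or the hairpin-half midpoint.
    """
    refs = {hid: HairpinReference(hid, normalize_sequence(seq)) for hid, seq in hairpins.items()}
    for mature_id, hairpin_id, arm, start, end in annotations:
        if hairpin_id not in refs:
            raise ValueError(
                f"mature {mature_id!r} references unknown hairpin {hairpin_id!r}"
            )
        hp = refs[hairpin_id]
        if not (0 <= start < end <= len(hp.sequence)):
            raise ValueError(
                f"mature {mature_id!r}: span [{start}, {end}) outside hairpin "
                f"{hairpin_id!r} (length {len(hp.sequence)})"
            )
        if arm is None:
            arm = _infer_arm(mature_id, start, end, len(hp.sequence))
        hp.matures.append(
            MatureAnnotation(
                mature_id=mature_id,
                arm=arm,
                start=start,
                end=end,
                canonical_sequence=hp.sequence[start:end],
            )
        )
    return ReferenceSet(refs)


def load_mature_annotations(
    gff3_path: str | Path, hairpins: Mapping[str, str]
) -> ReferenceSet:
    """Load mature coordinates from a miRBase-dialect GFF3.

    Expects feature type ``miRNA`` on hairpin-named landmarks with 1-based
    inclusive coordinates; the mature id is taken from the ``Name`` (or
    ``ID``) attribute.
    """
    gff3_path = Path(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    annotations = []
    for feat in db.features_of_type("miRNA", order_by="start"):
        name = feat.attributes.get("Name", feat.attributes.get("ID"))
        if not name:
            raise ValueError(f"{gff3_path}: miRNA feature without Name/ID attribute")
        mature_id = name[0]
        if feat.seqid not in hairpins:
            raise ValueError(
                f"mature {mature_id!r} on unknown landmark {feat.seqid!r}"
            )
        # GFF3 1-based inclusive -> 0-based half-open
        annotations.append((mature_id, feat.seqid, None, feat.start - 1, feat.end))
    if not annotations:
        raise ValueError(f"no miRNA features found in {gff3_path}")
    return build_reference(hairpins, annotations)


def load_mature_table(
    tsv_path: str | Path, hairpins: Mapping[str, str]
) -> ReferenceSet:
    """Load matures from a 5-column TSV (toy-reference alternative to GFF3).

    Columns: mature_id, hairpin_id, arm, start, end (1-based inclusive).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"arm": str})
    required = {"mature_id", "hairpin_id", "arm", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {sorted(missing)}")
    annotations = [
        (row.mature_id, row.hairpin_id, row.arm, int(row.start) - 1, int(row.end))
        for row in df.itertuples()
    ]
    return build_reference(hairpins, annotations)


def write_reference(
    ref: ReferenceSet, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write a reference back to FASTA + GFF3 (round-trip compatible)."""
    with open(fasta_path, "w") as fa:
        for hp in ref.hairpins.values():
            fa.write(f">{hp.hairpin_id}\n{hp.sequence}\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for hp, mat in ref.iter_matures():
            attrs = f"ID={mat.mature_id};Name={mat.mature_id}"
            gff.write(
                f"{hp.hairpin_id}\t.\tmiRNA\t{mat.start + 1}\t{mat.end}\t.\t+\t.\t{attrs}\n"
            )
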