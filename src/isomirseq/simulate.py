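"""Ground-truth small-RNA library simulator.

Generates toy hairpin references and two-condition, replicated FASTQ
libraries with *known* miRNA abundances and isomiR mixtures, so every
pipeline stage can be checked against a machine-readable truth table.
What it emulates: mature-derived inserts with designed 5'/3' end offsets
and optional non-templated tails, read-through into the literal 3'
ligation adapter at a fixed read length, Phred+33 quality strings with a
designed fraction of low-quality reads, per-base substitution errors, and
a configurable between-condition shift in isomiR composition or total
abundance for selected miRNAs.  What it does not emulate: ligation bias,
PCR duplicates, indels, or platform-specific quality profiles.

Replicate-to-replicate biological variability is modelled as a small
multiplicative log-normal jitter on both miRNA abundance weights and
isomiR mixture probabilities, independently per library; sampling
variability on top is multinomial.  Everything is deterministic under a
seed (same seed, byte-identical reads and truth).
"""

from __future__ import annotations

import copy
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import edlib
import numpy as np
import pandas as pd
import yaml

from .caller import Candidate, CallerParams, IsomiRCaller, isomir_label
from .preprocess import DEFAULT_ADAPTER
from .reference import ReferenceSet, build_reference, write_reference

__all__ = [
    "IsoClass",
    "SimDesign",
    "SampleReads",
    "TruthTable",
    "SimResult",
    "make_toy_reference",
    "default_design",
    "simulate_libraries",
    "null_and_effect_scenarios",
    "ScenarioBundle",
]

# fixed post-adapter filler so reads of equal insert collapse to one string
_FILLER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGC"

CONTROL, TREATED = "control", "treated"


class IsoClass(NamedTuple):
    """A designed isomiR class: end offsets plus optional non-templated tail."""

    offset5: int = 0
    offset3: int = 0
    tail: str = ""

    @property
    def label(self) -> str:
        return isomir_label(
            Candidate("", self.offset5, self.offset3, not self.tail, self.tail, 0)
        )

    def encode(self) -> str:
        return f"{self.offset5},{self.offset3},{self.tail}"

    @classmethod
    def decode(cls, text: str) -> "IsoClass":
        o5, o3, tail = text.split(",")
        return cls(int(o5), int(o3), tail)


@dataclass
class SimDesign:
    """Generative settings for one two-condition experiment.

    ``abundance[condition][mature_id]`` are relative weights (normalised
    per library); ``mixture[condition][mature_id]`` maps
    :class:`IsoClass` to probabilities summing to one.
    """

    abundance: dict[str, dict[str, float]]
    mixture: dict[str, dict[str, dict[IsoClass, float]]]
    reads_per_sample: int = 200_000
    replicates: int = 3
    error_rate: float = 0.001
    low_quality_fraction: float = 0.02
    mean_quality: int = 38
    read_length: int = 50
    adapter: str = DEFAULT_ADAPTER
    replicate_noise_sd: float = 0.02

    @property
    def conditions(self) -> list[str]:
        return list(self.abundance)

    def validate(self, ref: ReferenceSet, params: CallerParams | None = None) -> None:
        """Fail before any I/O if the design leaves the caller window.

        Every designed class must reconstruct to an insert that the
        caller resolves, unambiguously, to its generating (mature, label)
        — the precondition for truth-table accounting to be meaningful.
        """
        params = params or CallerParams()
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.low_quality_fraction < 1):
            raise ValueError("low_quality_fraction must be in [0, 1)")
        caller = IsomiRCaller(ref, params)
        for cond in self.conditions:
            for mature_id, classes in self.mixture[cond].items():
                total = sum(classes.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"mixture for {mature_id} in {cond!r} sums to {total}"
                    )
                for cls in classes:
                    insert = _class_insert(ref, mature_id, cls)
                    call = caller.call(insert)
                    if call is None or call.ambiguous:
                        raise ValueError(
                            f"class {cls} of {mature_id} is unresolvable/ambiguous"
                        )
                    if call.mature_id != mature_id or call.label != cls.label:
                        raise ValueError(
                            f"class {cls} of {mature_id} resolves to "
                            f"({call.mature_id}, {call.label}), not its own label"
                        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "abundance": self.abundance,
            "mixture": {
                cond: {
                    mid: {cls.encode(): p for cls, p in classes.items()}
                    for mid, classes in per_mirna.items()
                }
                for cond, per_mirna in self.mixture.items()
            },
            "reads_per_sample": self.reads_per_sample,
            "replicates": self.replicates,
            "error_rate": self.error_rate,
            "low_quality_fraction": self.low_quality_fraction,
            "mean_quality": self.mean_quality,
            "read_length": self.read_length,
            "adapter": self.adapter,
            "replicate_noise_sd": self.replicate_noise_sd,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimDesign":
        doc = yaml.safe_load(Path(path).read_text())
        mixture = {
            cond: {
                mid: {IsoClass.decode(k): float(p) for k, p in classes.items()}
                for mid, classes in per_mirna.items()
            }
            for cond, per_mirna in doc["mixture"].items()
        }
        return cls(
            abundance={c: dict(v) for c, v in doc["abundance"].items()},
            mixture=mixture,
            reads_per_sample=int(doc["reads_per_sample"]),
            replicates=int(doc["replicates"]),
            error_rate=float(doc["error_rate"]),
            low_quality_fraction=float(doc["low_quality_fraction"]),
            mean_quality=int(doc["mean_quality"]),
            read_length=int(doc["read_length"]),
            adapter=str(doc["adapter"]),
            replicate_noise_sd=float(doc["replicate_noise_sd"]),
        )


def _class_insert(ref: ReferenceSet, mature_id: str, cls: IsoClass) -> str:
    hp, mat = ref.mature(mature_id)
    start = mat.start - cls.offset5
    end = mat.end + cls.offset3 - len(cls.tail)
    if start < 0 or end > len(hp.sequence) or end <= start:
        raise ValueError(f"class {cls} outside hairpin for {mature_id}")
    return hp.sequence[start:end] + cls.tail


@dataclass
class SampleReads:
    """Collapsed reads of one library: (bases, quals, count) entries."""

    sample: str
    condition: str
    experiment: int
    entries: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(n for _, _, n in self.entries)

    def iter_records(self) -> Iterator[tuple[str, str, str]]:
        """Expand to (read_id, bases, quals) records."""
        i = 0
        for bases, quals, n in self.entries:
            for _ in range(n):
                yield f"{self.sample}_read{i:07d}", bases, quals
                i += 1

    def write_fastq(self, path: str | Path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as out:
            for read_id, bases, quals in self.iter_records():
                out.write(f"@{read_id}\n{bases}\n+\n{quals}\n")


@dataclass
class TruthTable:
    """Realized per-sample, per-class read accounting.

    ``counts[sample][(mature_id, label)]`` holds ``emitted`` (all reads
    generated for the class), ``low_quality`` (designed to fail the
    quality rule) and ``errored`` (carrying >= 1 substitution; these stay
    mappable within a one-mismatch window but acquire a ``|m`` label).
    ``clean`` = emitted - low_quality - errored reads are the ones a
    perfect pipeline must count under the designed label.
    """

    reads_per_sample: int
    counts: dict[str, dict[tuple[str, str], dict[str, int]]] = field(
        default_factory=dict
    )
    designed_mixture: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )

    def clean_counts(self, sample: str) -> dict[tuple[str, str], int]:
        return {
            key: rec["emitted"] - rec["low_quality"] - rec["errored"]
            for key, rec in self.counts[sample].items()
        }

    def emitted_counts(self, sample: str) -> dict[tuple[str, str], int]:
        return {key: rec["emitted"] for key, rec in self.counts[sample].items()}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "reads_per_sample": self.reads_per_sample,
            "designed_mixture": self.designed_mixture,
            "counts": {
                sample: {f"{m}|{lab}": rec for (m, lab), rec in recs.items()}
                for sample, recs in self.counts.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


@dataclass
class SimResult:
    samples: dict[str, SampleReads]
    truth: TruthTable
    design: SimDesign
    design_table: pd.DataFrame  # sample, condition, experiment

    def collapsed(self, sample: str) -> list[tuple[str, str, int]]:
        return self.samples[sample].entries


def make_toy_reference(
    n_hairpins: int = 3,
    seed: int = 0,
    min_edit_distance: int = 6,
    flank: int = 5,
) -> ReferenceSet:
    """Random toy hairpins with one 5p and one 3p mature each.

    Layout: 5' flank, 5p mature (20-23 nt), loop (8-12 nt), 3p mature
    (20-23 nt), 3' flank — so every mature has templated flank available
    on both sides.  All canonical sequences are kept pairwise >= 6 edits
    apart (edlib), which keeps the caller window collision-free.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    hairpins: dict[str, str] = {}
    annotations: list[tuple[str, str, str | None, int, int]] = []
    accepted: list[str] = []
    for i in range(n_hairpins):
        for _attempt in range(1000):
            len5 = int(rng.integers(20, 24))
            len3 = int(rng.integers(20, 24))
            loop = int(rng.integers(8, 13))
            total = flank + len5 + loop + len3 + flank
            seq = "".join(rng.choice(bases, size=total))
            m5 = seq[flank : flank + len5]
            m3 = seq[flank + len5 + loop : flank + len5 + loop + len3]
            ok = _edit_distance(m5, m3) >= min_edit_distance and all(
                _edit_distance(new, old) >= min_edit_distance
                for new in (m5, m3)
                for old in accepted
            )
            if ok:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place distinct matures; relax constraints")
        hid = f"toy-mir-{i + 1}"
        hairpins[hid] = seq
        accepted.extend([m5, m3])
        annotations.append(
            (f"toy-miR-{i + 1}-5p", hid, "5p", flank, flank + len5)
        )
        start3 = flank + len5 + loop
        annotations.append((f"toy-miR-{i + 1}-3p", hid, "3p", start3, start3 + len3))
    return build_reference(hairpins, annotations)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _pick_tail_base(ref: ReferenceSet, mature_id: str) -> str:
    """A 1-nt tail guaranteed non-templated (differs from the 3' flank)."""
    flank = ref.templated_flank(mature_id, "3prime", 1)
    for base in "TACG":  # prefer T: uridylation analogue
        if base != flank:
            return base
    raise AssertionError("unreachable")


def default_design(
    ref: ReferenceSet,
    reads_per_sample: int = 200_000,
    replicates: int = 3,
    **overrides,
) -> SimDesign:
    """Study-shaped base design: 2 conditions x 3 replicates, no effect.

    Abundance weights decay across matures (1/(rank+1)) so the library has
    a realistic skew; every mature gets the same isomiR mixture —
    canonical-dominated with shorter 3' isoforms and a small
    non-templated tail class: {0: 0.60, -1: 0.25, -3: 0.10, tail: 0.05}.
    """
    mature_ids = ref.mature_ids()
    weights = {mid: 1.0 / (rank + 1) for rank, mid in enumerate(mature_ids)}
    mixture_one = {
        mid: {
            IsoClass(0, 0, ""): 0.60,
            IsoClass(0, -1, ""): 0.25,
            IsoClass(0, -3, ""): 0.10,
            IsoClass(0, 1, _pick_tail_base(ref, mid)): 0.05,
        }
        for mid in mature_ids
    }
    design = SimDesign(
        abundance={CONTROL: dict(weights), TREATED: dict(weights)},
        mixture={
            CONTROL: copy.deepcopy(mixture_one),
            TREATED: copy.deepcopy(mixture_one),
        },
        reads_per_sample=reads_per_sample,
        replicates=replicates,
        **overrides,
    )
    return design


@dataclass
class ScenarioBundle:
    """Null / proportion-shift / abundance designs sharing one base."""

    null: SimDesign
    proportion_shift: SimDesign
    abundance: SimDesign
    target_mature: str  # proportion-shift target
    abundance_target: str


def null_and_effect_scenarios(
    base: SimDesign,
    target_mature: str | None = None,
    abundance_target: str | None = None,
    canonical_shift: tuple[float, float] = (0.60, 0.45),
    abundance_factor: float = 0.5,
) -> ScenarioBundle:
    """Derive the three standard scenarios from a base design.

    * *null*: both conditions share the base generative settings.
    * *proportion shift*: the target miRNA's canonical class moves from
      ``canonical_shift[0]`` to ``canonical_shift[1]`` in the treated
      condition, fully compensated by the -3 (shorter) class — the
      "canonical down, shorter isoform up" template.
    * *abundance*: the abundance target's expected abundance is scaled by
      ``abundance_factor`` in the treated condition, a designed absolute
      log2 fold change of ``log2(abundance_factor)``.

    The abundance target defaults to the *least* abundant mature: RPM is
    compositional, so a changed miRNA occupying a large library share
    drags the denominator with it and its RPM fold change understates the
    absolute one.  Keeping the target's share small (as any single miRNA's
    share is in a real library with hundreds of species) keeps that
    distortion below ~0.04 log2 units in the toy designs.
    """
    if target_mature is None:
        target_mature = next(iter(base.mixture[CONTROL]))
    if abundance_target is None:
        abundance_target = min(
            base.abundance[CONTROL], key=lambda m: base.abundance[CONTROL][m]
        )
    null = copy.deepcopy(base)

    prop = copy.deepcopy(base)
    before, after = canonical_shift
    classes = prop.mixture[TREATED][target_mature]
    canon = IsoClass(0, 0, "")
    shorter = IsoClass(0, -3, "")
    if not np.isclose(classes[canon], before):
        raise ValueError(
            f"base canonical proportion {classes[canon]} != expected {before}"
        )
    delta = before - after
    classes[canon] = after
    classes[shorter] = classes[shorter] + delta

    abund = copy.deepcopy(base)
    abund.abundance[TREATED][abundance_target] *= abundance_factor
    return ScenarioBundle(null, prop, abund, target_mature, abundance_target)


def _jitter(rng: np.random.Generator, probs: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return probs / probs.sum()
    jittered = probs * np.exp(rng.normal(0.0, sd, size=len(probs)))
    return jittered / jittered.sum()


def _low_quality_string(read_length: int, mean_quality: int) -> str:
    # > 10% of cycles below Q30 at the 3' end => fails the 90/30 rule
    n_bad = read_length // 10 + 1
    good = chr(33 + mean_quality) * (read_length - n_bad)
    return good + chr(33 + 2) * n_bad


def _simulate_sample(
    design: SimDesign,
    ref: ReferenceSet,
    condition: str,
    experiment: int,
    rng: np.random.Generator,
    sample: str,
) -> tuple[SampleReads, dict[tuple[str, str], dict[str, int]]]:
    mature_ids = [m for m in ref.mature_ids() if m in design.abundance[condition]]
    weights = np.array([design.abundance[condition][m] for m in mature_ids])
    weights = _jitter(rng, weights, design.replicate_noise_sd)

    # joint (mature, class) probabilities for one multinomial draw
    keys: list[tuple[str, IsoClass]] = []
    probs: list[float] = []
    for mid, w in zip(mature_ids, weights):
        classes = design.mixture[condition][mid]
        cls_list = sorted(classes, key=lambda c: (c.offset5, c.offset3, c.tail))
        cls_probs = _jitter(
            rng, np.array([classes[c] for c in cls_list]), design.replicate_noise_sd
        )
        for cls, p in zip(cls_list, cls_probs):
            keys.append((mid, cls))
            probs.append(w * p)
    probs_arr = np.array(probs)
    probs_arr /= probs_arr.sum()
    counts = rng.multinomial(design.reads_per_sample, probs_arr)

    good_qual = chr(33 + design.mean_quality) * design.read_length
    low_qual = _low_quality_string(design.read_length, design.mean_quality)
    base_choices = "ACGT"

    reads = SampleReads(sample=sample, condition=condition, experiment=experiment)
    truth: dict[tuple[str, str], dict[str, int]] = {}
    for (mid, cls), n in zip(keys, counts):
        n = int(n)
        insert = _class_insert(ref, mid, cls)
        read = (insert + design.adapter + _FILLER)[: design.read_length]
        label = cls.label
        rec = truth.setdefault(
            (mid, label), {"emitted": 0, "low_quality": 0, "errored": 0}
        )
        rec["emitted"] += n
        if n == 0:
            continue
        n_low = int(rng.binomial(n, design.low_quality_fraction))
        n_good = n - n_low
        n_err = 0
        mutated: dict[str, int] = {}
        if design.error_rate > 0 and n_good > 0:
            err_counts = rng.binomial(len(insert), design.error_rate, size=n_good)
            for k in err_counts[err_counts > 0]:
                pos = rng.choice(len(insert), size=int(k), replace=False)
                chars = list(insert)
                for p in pos:
                    old = chars[p]
                    choices = base_choices.replace(old, "")
                    chars[p] = choices[int(rng.integers(0, 3))]
                mutread = ("".join(chars) + design.adapter + _FILLER)[
                    : design.read_length
                ]
                mutated[mutread] = mutated.get(mutread, 0) + 1
                n_err += 1
        rec["low_quality"] += n_low
        rec["errored"] += n_err
        n_clean = n_good - n_err
        if n_clean > 0:
            reads.entries.append((read, good_qual, n_clean))
        if n_low > 0:
            reads.entries.append((read, low_qual, n_low))
        for mutread, mcount in sorted(mutated.items()):
            reads.entries.append((mutread, good_qual, mcount))
    return reads, truth


def simulate_libraries(
    design: SimDesign,
    ref: ReferenceSet,
    seed: int = 0,
    outdir: str | Path | None = None,
    validate: bool = True,
) -> SimResult:
    """Simulate all libraries of a design; optionally write files.

    Samples are named ``<condition>_<experiment>``; experiment numbers
    pair the two conditions (libraries prepared from the same culture).
    When ``outdir`` is given, per-sample ``<sample>.fastq.gz``, the
    reference (``hairpins.fa`` + ``matures.gff3``), ``truth.json`` and
    ``design.yaml`` are written there.
    """
    if validate:
        design.validate(ref)
    truth = TruthTable(reads_per_sample=design.reads_per_sample)
    for cond in design.conditions:
        truth.designed_mixture[cond] = {
            mid: {cls.label: p for cls, p in classes.items()}
            for mid, classes in design.mixture[cond].items()
        }
    samples: dict[str, SampleReads] = {}
    rows = []
    for ci, cond in enumerate(design.conditions):
        for r in range(design.replicates):
            sample = f"{cond}_{r + 1}"
            rng = np.random.default_rng([seed, ci, r])
            reads, sample_truth = _simulate_sample(
                design, ref, cond, r + 1, rng, sample
            )
            samples[sample] = reads
            truth.counts[sample] = sample_truth
            rows.append({"sample": sample, "condition": cond, "experiment": r + 1})
    design_table = pd.DataFrame(rows)
    result = SimResult(
        samples=samples, truth=truth, design=design, design_table=design_table
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reference(ref, outdir / "hairpins.fa", outdir / "matures.gff3")
        for sample, reads in samples.items():
            reads.write_fastq(outdir / f"{sample}.fastq.gz")
        truth.to_json(outdir / "truth.json")
        design.to_yaml(outdir / "design.yaml")
    return result
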