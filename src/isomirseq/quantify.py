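"""Count tables, RPM normalisation, abundance filters, proportions, arm ratios.

Quantification happens at two resolutions: isomiR rows keyed by
``(mature_id, label)`` and miRNA rows (sum over labels).  RPM (reads per
million) uses the total miRNA-mapped reads of each sample as denominator
by default — the standard miRNA-seq choice, robust to non-miRNA
contamination — with the clean-read total as a configurable alternative.

Abundance filters follow the usual two-tier rule: a mature miRNA is
analysed only if its mean RPM reaches 10 in at least one condition, an
isomiR only if it reaches 1 RPM in at least one condition (boundaries
inclusive).

IsomiR *proportions* divide each label's count by the total count of its
miRNA in that sample, restricted by default to templated labels
(non-templated tails are excluded from numerator and denominator).  A
miRNA/sample cell with zero denominator is *missing* (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import IsomiRCall, is_templated_label, label_sort_key
from .reference import ReferenceSet

__all__ = [
    "CountTables",
    "build_counts",
    "rpm_normalize",
    "filter_mature",
    "filter_isomirs",
    "isomir_proportions",
    "arm_ratio",
    "motif_count",
    "reconstruct_sequence",
]

MATURE_RPM_THRESHOLD = 10.0
ISOMIR_RPM_THRESHOLD = 1.0


def _condition_means(rpm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean RPM per condition (columns) from a sample-level matrix."""
    groups = design.groupby("condition")["sample"].apply(list)
    return pd.DataFrame(
        {cond: rpm[samples].mean(axis=1) for cond, samples in groups.items()}
    )


@dataclass
class CountTables:
    """Raw and RPM-normalised counts at isomiR and miRNA resolution."""

    isomir_counts: pd.DataFrame  # MultiIndex (mature_id, label) x samples
    mirna_counts: pd.DataFrame  # mature_id x samples
    library_sizes: pd.Series  # per-sample RPM denominator
    isomir_rpm: pd.DataFrame
    mirna_rpm: pd.DataFrame

    def check(self) -> None:
        summed = self.isomir_counts.groupby(level="mature_id", sort=False).sum()
        if not summed.equals(self.mirna_counts):
            raise AssertionError("mirna_counts is not the label-sum of isomir_counts")


def _sorted_index(keys: Iterable[tuple[str, str]]) -> pd.MultiIndex:
    ordered = sorted(set(keys), key=lambda k: (k[0], label_sort_key(k[1])))
    return pd.MultiIndex.from_tuples(ordered, names=["mature_id", "label"])


def build_counts(
    per_sample: Mapping[str, Mapping[tuple[str, str], int] | Sequence[IsomiRCall]],
    library_sizes: Mapping[str, int] | None = None,
) -> CountTables:
    """Assemble count tables from per-sample calls.

    ``per_sample`` maps sample id to either ``(mature_id, label) -> count``
    or a sequence of :class:`IsomiRCall`.  Absent (feature, sample) pairs
    are zero-filled.  Row order is deterministic: mature id, then
    canonical label first, then 3' offsets ascending, then 5' and tail
    labels.  ``library_sizes`` overrides the RPM denominator (default:
    miRNA-mapped reads, i.e. column sums).
    """
    samples = list(per_sample)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample ids")
    normalized: dict[str, Mapping[tuple[str, str], int]] = {}
    for sample, data in per_sample.items():
        if isinstance(data, Mapping):
            normalized[sample] = data
        else:
            counts: dict[tuple[str, str], int] = {}
            for call in data:
                key = (call.mature_id, call.label)
                counts[key] = counts.get(key, 0) + 1
            normalized[sample] = counts
    all_keys = [k for counts in normalized.values() for k in counts]
    index = _sorted_index(all_keys)
    isomir = pd.DataFrame(0, index=index, columns=samples, dtype=np.int64)
    for sample, counts in normalized.items():
        for key, n in counts.items():
            isomir.loc[key, sample] = n
    mirna = isomir.groupby(level="mature_id", sort=False).sum()
    if library_sizes is not None:
        libs = pd.Series({s: int(library_sizes[s]) for s in samples})
    else:
        libs = isomir.sum(axis=0)
    libs.name = "library_size"
    # samples with no mapped reads get NaN RPM columns rather than an error
    safe = libs.where(libs > 0, other=np.nan)
    isomir_rpm = isomir.div(safe[isomir.columns], axis=1) * 1e6
    tables = CountTables(
        isomir_counts=isomir,
        mirna_counts=mirna,
        library_sizes=libs,
        isomir_rpm=isomir_rpm,
        mirna_rpm=mirna.div(safe[mirna.columns], axis=1) * 1e6,
    )
    tables.check()
    return tables


def rpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """counts / denominator * 1e6, column-wise."""
    for sample in counts.columns:
        if library_sizes[sample] <= 0:
            raise ValueError(f"sample {sample!r}: non-positive RPM denominator")
    return counts.div(library_sizes[counts.columns], axis=1) * 1e6


def filter_mature(
    mirna_rpm: pd.DataFrame,
    design: pd.DataFrame,
    threshold: float = MATURE_RPM_THRESHOLD,
) -> list[str]:
    """Matures with mean RPM >= threshold in at least one condition."""
    means = _condition_means(mirna_rpm, design)
    keep = (means >= threshold).any(axis=1)
    return [m for m in mirna_rpm.index if keep[m]]


def filter_isomirs(
    isomir_rpm: pd.DataFrame,
    design: pd.DataFrame,
    threshold: float = ISOMIR_RPM_THRESHOLD,
) -> list[tuple[str, str]]:
    """IsomiR rows with mean RPM >= threshold in at least one condition."""
    means = _condition_means(isomir_rpm, design)
    keep = (means >= threshold).any(axis=1)
    return [k for k in isomir_rpm.index if keep[k]]


def isomir_proportions(
    isomir_counts: pd.DataFrame, templated_only: bool = True
) -> pd.DataFrame:
    """Per-(miRNA, sample) label proportions.

    Each label's count divided by the total count of its miRNA in that
    sample.  With ``templated_only`` (default), non-templated tail labels
    are dropped from both numerator and denominator, so proportions are
    over the templated classes only.  Zero-denominator cells are NaN
    (missing), not zero.
    """
    counts = isomir_counts
    if templated_only:
        mask = [is_templated_label(lab) for _, lab in counts.index]
        counts = counts.loc[mask]
    totals = counts.groupby(level="mature_id", sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / totals
    return props.where(totals > 0)


def arm_ratio(
    mirna_rpm: pd.DataFrame,
    ref: ReferenceSet,
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """log2((5p RPM + eps) / (3p RPM + eps)) per hairpin with both arms.

    Hairpins missing either arm annotation, or whose arms were not
    quantified, are excluded.  Antisymmetric under arm swap by
    construction.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    rows = {}
    for hairpin_id in ref.hairpins_with_both_arms():
        hp = ref.hairpins[hairpin_id]
        m5 = hp.mature_for_arm("5p")
        m3 = hp.mature_for_arm("3p")
        assert m5 is not None and m3 is not None
        if m5.mature_id not in mirna_rpm.index or m3.mature_id not in mirna_rpm.index:
            continue
        rows[hairpin_id] = np.log2(
            (mirna_rpm.loc[m5.mature_id] + epsilon)
            / (mirna_rpm.loc[m3.mature_id] + epsilon)
        )
    return pd.DataFrame(rows).T


def motif_count(
    sequences: Mapping[str, str] | pd.Series, motif: str = "TAAAT"
) -> tuple[pd.Series, float]:
    """Substring presence of ``motif`` per sequence, plus the aggregate fraction.

    The default motif is the AU-rich UAAAU element in DNA alphabet.
    """
    seqs = pd.Series(dict(sequences)) if not isinstance(sequences, pd.Series) else sequences
    motif = motif.upper().replace("U", "T")
    hits = seqs.str.upper().str.replace("U", "T").str.contains(motif, regex=False)
    fraction = float(hits.mean()) if len(hits) else float("nan")
    return hits, fraction


def reconstruct_sequence(
    ref: ReferenceSet,
    mature_id: str,
    offset5: int = 0,
    offset3: int = 0,
    nt_tail: str = "",
) -> str:
    """Rebuild the (error-free) isomiR sequence implied by a call."""
    hp, mat = ref.mature(mature_id)
    start = mat.start - offset5
    end = mat.end + offset3 - len(nt_tail)
    if start < 0 or end > len(hp.sequence) or end <= start:
        raise ValueError(
            f"offsets ({offset5}, {offset3}) invalid for {mature_id}"
        )
    return hp.sequence[start:end] + nt_tail
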