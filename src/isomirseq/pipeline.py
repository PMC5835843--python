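"""End-to-end orchestration: reads -> clean inserts -> calls -> tables -> tests.

The collapsed path (unique read sequences with multiplicities) is used
throughout — small-RNA libraries are redundant enough that this makes the
whole pipeline run in time linear in *unique* reads.  The file-based path
(`run_fastq_sample`) streams a FASTQ and collapses on the fly, so both
paths share the per-read logic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .caller import CallerParams, CallSummary, IsomiRCaller, call_collapsed
from .preprocess import (
    PreprocessParams,
    PreprocessReport,
    preprocess_collapsed,
    read_fastq,
)
from .quantify import CountTables, build_counts, filter_mature, isomir_proportions
from .reference import ReferenceSet
from .differential import TestSpec, isomir_proportion_test, mirna_volcano
from .simulate import SimResult

__all__ = [
    "SampleResult",
    "ExperimentResult",
    "run_collapsed_sample",
    "run_fastq_sample",
    "run_experiment",
    "analyze_experiment",
]


@dataclass
class SampleResult:
    label_counts: dict[tuple[str, str], int]
    preprocess_report: PreprocessReport
    call_summary: CallSummary


@dataclass
class ExperimentResult:
    tables: CountTables
    design: pd.DataFrame
    reports: dict[str, PreprocessReport]
    summaries: dict[str, CallSummary]


def run_collapsed_sample(
    entries: Iterable[tuple[str, str, int]],
    ref: ReferenceSet,
    pp_params: PreprocessParams | None = None,
    caller_params: CallerParams | None = None,
    caller: IsomiRCaller | None = None,
) -> SampleResult:
    """Preprocess and call one library given collapsed (bases, quals, count)."""
    inserts, report = preprocess_collapsed(entries, pp_params)
    counts, summary = call_collapsed(
        inserts, ref, caller_params, caller=caller
    )
    return SampleResult(counts, report, summary)


def run_fastq_sample(
    fastq_path,
    ref: ReferenceSet,
    pp_params: PreprocessParams | None = None,
    caller_params: CallerParams | None = None,
    caller: IsomiRCaller | None = None,
) -> SampleResult:
    collapsed = Counter()
    for rec in read_fastq(fastq_path):
        collapsed[(rec.bases, rec.quals)] += 1
    return run_collapsed_sample(
        ((b, q, n) for (b, q), n in collapsed.items()),
        ref,
        pp_params,
        caller_params,
        caller,
    )


def run_experiment(
    sim: SimResult | Mapping[str, Iterable[tuple[str, str, int]]],
    ref: ReferenceSet,
    design: pd.DataFrame | None = None,
    pp_params: PreprocessParams | None = None,
    caller_params: CallerParams | None = None,
) -> ExperimentResult:
    """Run every sample of a simulated (or collapsed-read) experiment.

    A single memoising caller is shared across samples, so repeated
    sequences are resolved once per experiment.
    """
    if isinstance(sim, SimResult):
        per_sample = {s: sim.collapsed(s) for s in sim.samples}
        design = sim.design_table if design is None else design
    else:
        per_sample = dict(sim)
        if design is None:
            raise ValueError("design table required for raw collapsed input")
    caller = IsomiRCaller(ref, caller_params or CallerParams())
    label_counts: dict[str, dict[tuple[str, str], int]] = {}
    reports: dict[str, PreprocessReport] = {}
    summaries: dict[str, CallSummary] = {}
    for sample, entries in per_sample.items():
        res = run_collapsed_sample(entries, ref, pp_params, caller_params, caller)
        label_counts[sample] = res.label_counts
        reports[sample] = res.preprocess_report
        summaries[sample] = res.call_summary
    tables = build_counts(label_counts)
    return ExperimentResult(tables, design, reports, summaries)


@dataclass
class AnalysisResult:
    volcano: pd.DataFrame
    per_label: pd.DataFrame
    per_mirna: pd.DataFrame
    kept_matures: list[str]


def analyze_experiment(
    result: ExperimentResult,
    treated: str = "treated",
    control: str = "control",
    spec: TestSpec | None = None,
    templated_only: bool = True,
) -> AnalysisResult:
    """Abundance filter, volcano and per-label proportion tests."""
    spec = spec or TestSpec()
    kept = filter_mature(result.tables.mirna_rpm, result.design)
    volcano = mirna_volcano(
        result.tables.mirna_rpm, result.design, treated, control, spec, features=kept
    )
    props = isomir_proportions(result.tables.isomir_counts, templated_only)
    props_kept = props.loc[[k for k in props.index if k[0] in kept]]
    per_label, per_mirna = isomir_proportion_test(
        props_kept, result.design, treated, control, spec
    )
    return AnalysisResult(volcano, per_label, per_mirna, kept)
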