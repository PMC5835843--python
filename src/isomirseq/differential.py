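"""Replicate-level differential analysis.

Two spreadsheet-style two-tailed Student's t-test variants are provided,
named by the familiar ``TTEST`` nomenclature: *type 2* is the two-sample
pooled-variance (homoscedastic) test with ``n_a + n_b - 2`` degrees of
freedom; *type 3* is the Welch (heteroscedastic) test with Satterthwaite
degrees of freedom.  With ``paired=True`` the classic paired test is run
on per-experiment differences (one-sample t, ``n - 1`` df); the variant
flag then has no effect.

Two analyses are built on top:

* ``mirna_volcano`` — per-miRNA mean log2 fold change across paired
  experiments (with a pseudocount) against the t-test p-value, the
  classic volcano table; and
* ``isomir_proportion_test`` — per-(miRNA, label) tests on replicate
  isomiR proportions between conditions, with a per-miRNA flag for "any
  label significant".

Experiments pair treated and control libraries prepared from the same
culture, so the paired test is the default.  No multiple-testing
correction is applied to the ``significant`` flag (per-feature p < alpha);
a Benjamini-Hochberg column ``q_value`` is emitted alongside as a
clearly-separate extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestSpec",
    "t_test",
    "mirna_volcano",
    "isomir_proportion_test",
    "heatmap_matrix",
]

DEFAULT_EPSILON = 0.5  # RPM pseudocount for fold changes


@dataclass(frozen=True)
class TestSpec:
    variant: str = "type2"
    alpha: float = 0.05
    paired: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("type2", "type3"):
            raise ValueError("variant must be 'type2' or 'type3'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    spec: TestSpec | None = None,
) -> tuple[float, float]:
    """(t statistic, two-tailed p) for ``group_a`` vs ``group_b``.

    Degenerate zero-spread data (both groups constant with equal means —
    or, paired, all differences zero) returns ``(0.0, 1.0)`` by
    convention rather than NaN.
    """
    spec = spec or TestSpec()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if spec.paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if len(a) < 2:
            raise ValueError("paired test requires >= 2 pairs")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return (0.0, 1.0) if d.mean() == 0 else (math.copysign(math.inf, d.mean()), 0.0)
        t = d.mean() / (sd / math.sqrt(len(d)))
        return float(t), _two_tailed_p(t, len(d) - 1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample test requires >= 2 values per group")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        return (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
    if spec.variant == "type2":
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(pooled * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = diff / se
    return float(t), _two_tailed_p(t, df)


def _paired_samples(design: pd.DataFrame, treated: str, control: str) -> tuple[list[str], list[str]]:
    """Sample ids of treated/control columns ordered by experiment."""
    required = {"sample", "condition", "experiment"}
    if not required.issubset(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    by_exp = design.pivot(index="experiment", columns="condition", values="sample")
    for cond in (treated, control):
        if cond not in by_exp.columns or by_exp[cond].isna().any():
            raise ValueError(f"condition {cond!r} missing samples for some experiments")
    return list(by_exp[treated]), list(by_exp[control])


def mirna_volcano(
    mirna_rpm: pd.DataFrame,
    design: pd.DataFrame,
    treated: str,
    control: str,
    spec: TestSpec | None = None,
    epsilon: float = DEFAULT_EPSILON,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA volcano table: mean log2 fold change vs t-test p-value.

    ``design`` columns: sample, condition, experiment (replicate pairing).
    Per experiment the fold change log2((treated RPM + eps)/(control RPM +
    eps)) is computed and averaged; the p-value comes from the t-test on
    per-experiment log2(RPM + eps) values, paired by experiment under the
    default spec.  Output sorted by ascending p.
    """
    spec = spec or TestSpec()
    t_cols, c_cols = _paired_samples(design, treated, control)
    rpm = mirna_rpm if features is None else mirna_rpm.loc[list(features)]
    log_t = np.log2(rpm[t_cols].to_numpy() + epsilon)
    log_c = np.log2(rpm[c_cols].to_numpy() + epsilon)
    rows = []
    for i, feature in enumerate(rpm.index):
        fcs = log_t[i] - log_c[i]
        t_stat, p = t_test(log_t[i], log_c[i], spec)
        rows.append((feature, float(fcs.mean()), t_stat, p))
    out = pd.DataFrame(rows, columns=["feature_id", "mean_log2fc", "t_stat", "p_value"])
    out["significant"] = out["p_value"] < spec.alpha
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def isomir_proportion_test(
    proportions: pd.DataFrame,
    design: pd.DataFrame,
    treated: str,
    control: str,
    spec: TestSpec | None = None,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test each (miRNA, label) proportion between conditions.

    Rows with missing replicate cells drop those replicates (pairwise for
    the paired test); rows with fewer than ``min_replicates`` complete
    replicates per group are skipped (NaN p, ``tested=False``).

    Returns ``(per_label, per_mirna)``: the per-label table with mean
    proportions, difference, t and p; and a per-miRNA summary with
    ``canonical_significant``, ``canonical_direction`` and
    ``any_label_significant``.
    """
    spec = spec or TestSpec()
    t_cols, c_cols = _paired_samples(design, treated, control)
    rows = []
    for key in proportions.index:
        vals_t = proportions.loc[key, t_cols].to_numpy(dtype=float)
        vals_c = proportions.loc[key, c_cols].to_numpy(dtype=float)
        if spec.paired:
            ok = np.isfinite(vals_t) & np.isfinite(vals_c)
            vals_t, vals_c = vals_t[ok], vals_c[ok]
            enough = ok.sum() >= min_replicates
        else:
            vals_t = vals_t[np.isfinite(vals_t)]
            vals_c = vals_c[np.isfinite(vals_c)]
            enough = len(vals_t) >= min_replicates and len(vals_c) >= min_replicates
        mature_id, label = key
        if not enough:
            rows.append((mature_id, label, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        mean_t, mean_c = float(vals_t.mean()), float(vals_c.mean())
        t_stat, p = t_test(vals_t, vals_c, spec)
        rows.append(
            (mature_id, label, mean_t, mean_c, mean_t - mean_c, t_stat, p, True)
        )
    per_label = pd.DataFrame(
        rows,
        columns=[
            "mature_id",
            "label",
            "mean_treated",
            "mean_control",
            "delta",
            "t_stat",
            "p_value",
            "tested",
        ],
    )
    per_label["significant"] = per_label["p_value"] < spec.alpha
    tested = per_label[per_label["tested"]]
    q = pd.Series(np.nan, index=per_label.index)
    if len(tested):
        q.loc[tested.index] = multipletests(tested["p_value"], method="fdr_bh")[1]
    per_label["q_value"] = q

    summaries = []
    for mature_id, grp in per_label.groupby("mature_id", sort=False):
        canon = grp[grp["label"] == "0"]
        canon_sig = bool(canon["significant"].any())
        direction = 0.0
        if len(canon) and np.isfinite(canon["delta"].iloc[0]):
            direction = float(np.sign(canon["delta"].iloc[0]))
        summaries.append(
            (
                mature_id,
                canon_sig,
                direction,
                bool(grp["significant"].any()),
            )
        )
    per_mirna = pd.DataFrame(
        summaries,
        columns=[
            "mature_id",
            "canonical_significant",
            "canonical_direction",
            "any_label_significant",
        ],
    )
    return per_label, per_mirna


def heatmap_matrix(
    per_label: pd.DataFrame,
    mirnas: Sequence[str] | None = None,
    offsets: Sequence[int] = range(-3, 4),
) -> pd.DataFrame:
    """One-axis isomiR change matrix: miRNAs x 3' offsets (-3..+3).

    Cells hold the proportion difference (treated - control) for 3'-offset
    labels of reads with an unshifted 5' end; the canonical class sits in
    the "0" column.  Labels that do not exist are NaN (the "non-existing"
    squares of the usual heatmap rendering).
    """
    wanted = {("0" if o == 0 else f"{o:+d}"): o for o in offsets}
    sub = per_label[per_label["label"].isin(wanted)]
    mat = sub.pivot(index="mature_id", columns="label", values="delta")
    cols = ["0" if o == 0 else f"{o:+d}" for o in offsets]
    mat = mat.reindex(columns=cols)
    if mirnas is not None:
        mat = mat.reindex(index=list(mirnas))
    return mat
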