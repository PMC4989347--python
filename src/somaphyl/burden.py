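"""Deleterious-burden summaries per evolutionary subset and cohort associations.

"Predicted deleterious" means flagged damaging by at least ``vote_threshold``
of the five upstream protein-impact predictors whose votes arrive with the
annotation table; the predictors themselves are never run here.  Burden is
summarized per partition subset (Common / Unique-to-PTC / Unique-to-ANT),
optionally against an external comparison cohort of plain variant sets
(e.g. population blood exomes), and total per-tumor SNS counts are compared
across clinical groupings (BRAF status, the 45-year age dichotomy, sex,
stage, histology) with Welch t-tests or one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding_impact import CODING_CONSEQUENCES, NONSYN_CLASSES
from .partition import SUBSET_NAMES, TrioPartition
from .variant_io import Key, PatientRecord, VariantSet


@dataclass
class BurdenResult:
    """Per-patient/subset burden records plus Welch contrasts on rates."""

    records: pd.DataFrame
    #: subset -> (t, p): per-coding-variant deleterious rate vs the Common subset
    contrasts: dict[str, tuple[float, float]]
    vote_threshold: int


def _variant_votes(v, votes: Mapping[Key, int] | None) -> int:
    if votes is not None:
        return votes.get(v.key, 0)
    return v.deleterious_votes or 0


def _burden_row(pid: str, subset: str, variants, votes, threshold: int) -> dict:
    n_sns = n_coding = n_nonsyn = n_del = 0
    for v in variants:
        n_sns += 1
        if v.consequence in CODING_CONSEQUENCES:
            n_coding += 1
            if v.consequence in NONSYN_CLASSES:
                n_nonsyn += 1
                if _variant_votes(v, votes) >= threshold:
                    n_del += 1
    return {
        "patient_id": pid,
        "subset": subset,
        "n_sns": n_sns,
        "n_coding": n_coding,
        "n_nonsynonymous": n_nonsyn,
        "n_predicted_deleterious": n_del,
        "deleterious_rate": n_del / n_coding if n_coding else np.nan,
    }


def deleterious_burden(
    cohort_partitions: Mapping[str, TrioPartition],
    votes: Mapping[Key, int] | None = None,
    vote_threshold: int = 1,
    comparison_sets: Sequence[VariantSet] | None = None,
) -> BurdenResult:
    """Count predicted-deleterious variants per patient and subset.

    ``votes`` maps variant keys to 0-5 predictor votes; when omitted, each
    variant's own ``deleterious_votes`` annotation is used, with missing
    votes treated as 0.  Only non-synonymous (incl. stopgain/stoploss)
    variants can be deleterious, so per-record counts satisfy
    ``n_predicted_deleterious <= n_nonsynonymous <= n_sns``.  The rate
    denominator is the subset's coding SNS count.  ``comparison_sets``
    appends rows with subset label ``"comparison"`` (an external cohort,
    e.g. population blood samples).
    """
    if not 1 <= vote_threshold <= 5:
        raise ValueError("vote_threshold must be in 1..5")
    if votes is not None:
        covered = set(votes)
        n_nonsyn_missing = sum(
            1
            for part in cohort_partitions.values()
            for name in SUBSET_NAMES
            for v in part.subset(name)
            if v.consequence in NONSYN_CLASSES and v.key not in covered
        )
        if n_nonsyn_missing:
            warnings.warn(
                f"{n_nonsyn_missing} non-synonymous variants lack votes; treated as 0",
                stacklevel=2,
            )
    rows = []
    for pid, part in cohort_partitions.items():
        for name in SUBSET_NAMES:
            rows.append(_burden_row(pid, name, part.subset(name), votes, vote_threshold))
    for vs in comparison_sets or ():
        rows.append(_burden_row(vs.sample_id, "comparison", vs, votes, vote_threshold))
    records = pd.DataFrame(rows)
    rates = records[records["subset"].isin(SUBSET_NAMES)].pivot(
        index="patient_id", columns="subset", values="deleterious_rate"
    )
    contrasts = {}
    for name in ("unique_ptc", "unique_ant"):
        paired = rates[[name, "common"]].dropna()
        if len(paired) >= 2:
            t, p = stats.ttest_ind(paired[name], paired["common"], equal_var=False)
            contrasts[name] = (float(t), float(p))
    return BurdenResult(records=records, contrasts=contrasts, vote_threshold=vote_threshold)


GROUPINGS = ("braf", "age45", "sex", "stage", "histology")


@dataclass
class GroupBurden:
    """Mean total SNS count per clinical group, with the appropriate test."""

    grouping: str
    group_means: pd.Series
    group_sizes: pd.Series
    test: str | None  # "welch_t" | "anova" | None
    statistic: float | None
    p_value: float | None


def cohort_totals(
    cohort_partitions: Mapping[str, TrioPartition],
    manifest: Sequence[PatientRecord],
) -> pd.DataFrame:
    """Per-patient total PTC SNS counts joined with manifest covariates."""
    counts = {
        pid: len(part.common) + len(part.unique_ptc)
        for pid, part in cohort_partitions.items()
    }
    rows = []
    for p in manifest:
        if p.patient_id not in counts:
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "n_sns_ptc": counts[p.patient_id],
                "age": p.age,
                "sex": p.sex,
                "braf_mutant": p.braf_mutant,
                "tnm_stage": p.tnm_stage,
                "histology": p.histology,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def burden_by_group(
    totals: pd.DataFrame,
    grouping: str,
    age_cut: float = 45.0,
    count_col: str = "n_sns_ptc",
) -> GroupBurden:
    """Compare total SNS counts across a clinical grouping.

    ``age45`` dichotomizes at strictly-greater-than ``age_cut`` (default 45
    years; patients aged exactly 45 fall in the younger group).  Two groups
    are compared by Welch t-test, three or more by one-way ANOVA; degenerate
    group sizes yield means without a test.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    df = totals.copy()
    if grouping == "braf":
        df["group"] = df["braf_mutant"].map({True: "BRAF+", False: "BRAF-"})
    elif grouping == "age45":
        df["group"] = np.where(df["age"] > age_cut, f">{age_cut:g}", f"<={age_cut:g}")
        df.loc[df["age"].isna(), "group"] = None
    else:
        df["group"] = df[{"sex": "sex", "stage": "tnm_stage", "histology": "histology"}[grouping]]
    df = df.dropna(subset=["group", count_col])
    means = df.groupby("group")[count_col].mean()
    sizes = df.groupby("group")[count_col].size()
    groups = [g[count_col].to_numpy(float) for _, g in df.groupby("group")]
    test = stat = p = None
    if len(groups) == 2 and all(len(g) >= 2 for g in groups):
        test = "welch_t"
        stat, p = stats.ttest_ind(*groups, equal_var=False)
        stat, p = float(stat), float(p)
    elif len(groups) > 2 and all(len(g) >= 2 for g in groups):
        test = "anova"
        stat, p = stats.f_oneway(*groups)
        stat, p = float(stat), float(p)
    else:
        warnings.warn(f"degenerate group sizes for {grouping}: means only", stacklevel=2)
    return GroupBurden(
        grouping=grouping,
        group_means=means,
        group_sizes=sizes,
        test=test,
        statistic=stat,
        p_value=p,
    )
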