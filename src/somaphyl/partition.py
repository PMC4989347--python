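"""Evolutionary partitioning of matched tumor / adjacent-normal variant signatures.

Intersecting a tumor (PTC) SNS signature with its matched adjacent non-tumor
(ANT) signature splits each patient's variants at the inferred divergence of
malignant from non-malignant thyrocyte lineages:

* **Common** — present in both tissues; germline plus changes accrued before
  the lineages diverged.
* **Unique-to-PTC / Unique-to-ANT** — present in only one tissue; late somatic
  events acquired after divergence.

A matched blood sample, whose lineage diverged earlier still (at the split of
hematopoietic from thyroid progenitors), is intersected with each subset
individually: a high blood overlap for the Common subset and a low one for
the unique subsets is the signature of this branching order.

The overlap metric is directional: ``overlap(A relative to B) = |A ∩ B| / |A|``,
i.e. the fraction of A's SNSs also found in B.  Jaccard similarity is offered
as an alternative for the inter-patient heterogeneity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Key, VariantSet

SUBSET_NAMES = ("common", "unique_ptc", "unique_ant")


@dataclass
class TrioPartition:
    """Per-patient Common / Unique-to-PTC / Unique-to-ANT subsets."""

    patient_id: str
    common: VariantSet
    unique_ptc: VariantSet
    unique_ant: VariantSet
    #: subset -> fraction of the subset's SNSs found in matched blood
    blood_overlap: dict[str, float | None] | None = None
    shared_fraction_ptc: float | None = None

    def subset(self, name: str) -> VariantSet:
        if name not in SUBSET_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def partition_trio(
    ptc: VariantSet,
    ant: VariantSet,
    blood: VariantSet | None = None,
    patient_id: str | None = None,
) -> TrioPartition:
    """Partition one patient's PTC/ANT signatures at the lineage branch point.

    Pure set algebra on (chrom, pos, ref, alt) keys.  When a blood signature
    is supplied, ``blood_overlap[s] = |s ∩ blood| / |s|`` is recorded for each
    subset; the fraction is ``None`` for an empty subset (reported missing
    rather than zero so cohort means are not biased).
    """
    if patient_id is None:
        patient_id = ptc.sample_id
    ptc_keys, ant_keys = ptc.keys(), ant.keys()
    common_keys = ptc_keys & ant_keys
    common = ptc.subset(common_keys, sample_id=patient_id)
    unique_ptc = ptc.subset(ptc_keys - ant_keys, sample_id=patient_id)
    unique_ant = ant.subset(ant_keys - ptc_keys, sample_id=patient_id)

    blood_overlap = None
    if blood is not None:
        blood_keys = blood.keys()
        blood_overlap = {}
        for name, keys in (
            ("common", common_keys),
            ("unique_ptc", ptc_keys - ant_keys),
            ("unique_ant", ant_keys - ptc_keys),
        ):
            blood_overlap[name] = len(keys & blood_keys) / len(keys) if keys else None

    shared = len(common_keys) / len(ptc_keys) if ptc_keys else None
    return TrioPartition(
        patient_id=patient_id,
        common=common,
        unique_ptc=unique_ptc,
        unique_ant=unique_ant,
        blood_overlap=blood_overlap,
        shared_fraction_ptc=shared,
    )


def partition_cohort(
    cohort: Mapping[str, Mapping[str, VariantSet]]
) -> dict[str, TrioPartition]:
    """Partition every patient of a loaded cohort.

    ``cohort`` maps patient id to ``{"PTC": vs, "ANT": vs, "BLOOD": vs?}``
    (the shape :func:`somaphyl.variant_io.load_cohort` returns).
    """
    out = {}
    for pid, samples in cohort.items():
        out[pid] = partition_trio(
            samples["PTC"], samples["ANT"], samples.get("BLOOD"), patient_id=pid
        )
    return out


@dataclass
class OverlapResult:
    """Full asymmetric inter-patient overlap matrix plus summary means."""

    matrix: pd.DataFrame  # rows i, cols j: |S_i ∩ S_j| / |S_i|; diagonal NaN
    per_patient_mean: pd.Series  # mean over j != i, NaN rows excluded
    cohort_mean: float


def overlap_matrix(
    sets: Mapping[str, set[Key]], metric: str = "directional"
) -> OverlapResult:
    """Pairwise overlap of named key sets.

    ``directional`` (default): entry (i, j) is the fraction of set i's keys
    found in set j.  ``jaccard``: |i ∩ j| / |i ∪ j| (symmetric).  Rows for
    empty sets are undefined (NaN) and excluded from means.
    """
    if metric not in {"directional", "jaccard"}:
        raise ValueError(f"unknown metric {metric!r}")
    ids = list(sets)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples for pairwise overlap")
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in ids:
        si = sets[i]
        for j in ids:
            if i == j:
                continue
            sj = sets[j]
            if metric == "directional":
                mat.loc[i, j] = len(si & sj) / len(si) if si else np.nan
            else:
                union = len(si | sj)
                mat.loc[i, j] = len(si & sj) / union if union else np.nan
    per_patient = mat.mean(axis=1, skipna=True)
    return OverlapResult(
        matrix=mat,
        per_patient_mean=per_patient,
        cohort_mean=float(per_patient.mean(skipna=True)),
    )


def pairwise_overlap(
    subset_name: str,
    cohort_partitions: Mapping[str, TrioPartition],
    metric: str = "directional",
) -> OverlapResult:
    """Inter-patient heterogeneity of one partition subset across the cohort."""
    sets = {
        pid: part.subset(subset_name).keys() for pid, part in cohort_partitions.items()
    }
    return overlap_matrix(sets, metric=metric)


@dataclass
class BloodConcordance:
    """Cohort means of blood-overlap fractions per subset, with Welch contrast."""

    mean_common: float
    mean_unique_ptc: float
    mean_unique_ant: float
    n_blood: int
    t_statistic: float | None
    p_value: float | None


def blood_concordance_summary(
    cohort_partitions: Mapping[str, TrioPartition]
) -> BloodConcordance:
    """Summarize how much of each subset is shared with matched blood.

    The Welch two-sample t-test contrasts the per-patient common-vs-blood
    fractions against the pooled unique-vs-blood fractions.  With fewer than
    two blood samples the means are returned without a test.
    """
    common, uniq = [], []
    for part in cohort_partitions.values():
        if part.blood_overlap is None:
            continue
        bo = part.blood_overlap
        if bo["common"] is not None:
            common.append(bo["common"])
        for name in ("unique_ptc", "unique_ant"):
            if bo[name] is not None:
                uniq.append((name, bo[name]))
    n_blood = sum(1 for p in cohort_partitions.values() if p.blood_overlap is not None)
    mean_uptc = float(np.mean([v for n, v in uniq if n == "unique_ptc"])) if uniq else np.nan
    mean_uant = float(np.mean([v for n, v in uniq if n == "unique_ant"])) if uniq else np.nan
    t_stat = p = None
    if n_blood >= 2 and len(common) >= 2 and len(uniq) >= 2:
        t_stat, p = stats.ttest_ind(
            common, [v for _, v in uniq], equal_var=False
        )
        t_stat, p = float(t_stat), float(p)
    else:
        warnings.warn("fewer than 2 blood samples: reporting means without a test",
                      stacklevel=2)
    return BloodConcordance(
        mean_common=float(np.mean(common)) if common else np.nan,
        mean_unique_ptc=mean_uptc,
        mean_unique_ant=mean_uant,
        n_blood=n_blood,
        t_statistic=t_stat,
        p_value=p,
    )


def partition_summary_table(
    cohort_partitions: Mapping[str, TrioPartition]
) -> pd.DataFrame:
    """One row per patient: subset sizes, shared fraction, blood overlaps."""
    rows = []
    for pid, part in cohort_partitions.items():
        row = {
            "patient_id": pid,
            "n_common": len(part.common),
            "n_unique_ptc": len(part.unique_ptc),
            "n_unique_ant": len(part.unique_ant),
            "n_ptc": len(part.common) + len(part.unique_ptc),
            "n_ant": len(part.common) + len(part.unique_ant),
            "shared_fraction_ptc": part.shared_fraction_ptc,
        }
        if part.blood_overlap is not None:
            for name in SUBSET_NAMES:
                row[f"blood_overlap_{name}"] = part.blood_overlap[name]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
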