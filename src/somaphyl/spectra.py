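"""Mutational spectra: strand-collapsed substitution classes, Tr:Tv ratios,
and spectrum-shift statistics.

Every single-nucleotide substitution is assigned to one of six strand-collapsed
classes (C>A, C>G, C>T, T>A, T>C, T>G) by representing the change in its
pyrimidine-reference orientation: a G>A on the reference strand is the same
chemical event as a C>T on the other strand, so both are counted as C>T.
The two transition classes are C>T and T>C; the other four are transversions.

Shift statistics treat the per-patient class proportion as the observational
unit (a cohort-level comparison, not a pooled-count one) and use the Welch
two-sample t-test, with one-way ANOVA for three or more subsets and a pooled
chi-square offered as a secondary diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Variant

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six strand-collapsed substitution classes, in canonical order.
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})

#: All twelve directed ref>alt substitutions.
DIRECTED = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def classify_substitution(ref: str, alt: str) -> str:
    """Map a directed substitution onto its strand-collapsed class.

    If the reference base is a pyrimidine (C or T) the class is ``ref>alt``;
    otherwise both bases are complemented first.
    """
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"bases must be in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def is_transition(label: str) -> bool:
    return label in TRANSITIONS


@dataclass
class SpectrumSummary:
    """Six-class substitution counts with proportions and the Tr:Tv ratio."""

    counts: dict[str, int]
    total: int
    proportions: dict[str, float]
    tr_tv_ratio: float | None

    def proportion(self, label: str) -> float | None:
        return self.proportions.get(label)


def spectrum(variants: Iterable[Variant], collapse: bool = True) -> SpectrumSummary:
    """Tally a variant collection into a :class:`SpectrumSummary`.

    With ``collapse=False`` the counts dict holds the twelve directed
    substitutions instead (proportions and Tr:Tv are computed the same way;
    transitions are A>G, G>A, C>T, T>C).
    """
    labels = CLASSES if collapse else DIRECTED
    counts = dict.fromkeys(labels, 0)
    for v in variants:
        label = classify_substitution(v.ref, v.alt) if collapse else f"{v.ref}>{v.alt}"
        counts[label] += 1
    total = sum(counts.values())
    props = {k: c / total for k, c in counts.items()} if total else {}
    tr = sum(c for k, c in counts.items() if classify_substitution(*k.split(">")) in TRANSITIONS)
    tv = total - tr
    return SpectrumSummary(
        counts=counts,
        total=total,
        proportions=props,
        tr_tv_ratio=(tr / tv) if tv else None,
    )


def trtv_fold_change(cohort_partitions: Mapping[str, "TrioPartition"]) -> pd.DataFrame:
    """Per-patient fold-change of the Common subset's Tr:Tv over each unique subset.

    Returns a DataFrame indexed by patient with columns ``trtv_common``,
    ``trtv_unique_ant``, ``trtv_unique_ptc``, ``fold_over_unique_ant``,
    ``fold_over_unique_ptc``.  Patients with an undefined Tr:Tv in any subset
    are excluded (all-transition or empty subsets).
    """
    rows = {}
    for pid, part in cohort_partitions.items():
        ratios = {
            "common": spectrum(part.common).tr_tv_ratio,
            "unique_ant": spectrum(part.unique_ant).tr_tv_ratio,
            "unique_ptc": spectrum(part.unique_ptc).tr_tv_ratio,
        }
        if any(r is None or r == 0 for r in ratios.values()):
            continue
        rows[pid] = {
            "trtv_common": ratios["common"],
            "trtv_unique_ant": ratios["unique_ant"],
            "trtv_unique_ptc": ratios["unique_ptc"],
            "fold_over_unique_ant": ratios["common"] / ratios["unique_ant"],
            "fold_over_unique_ptc": ratios["common"] / ratios["unique_ptc"],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ShiftTestResult:
    """Welch comparison of one substitution class between two subsets."""

    class_label: str
    mean_a: float
    mean_b: float
    effect: float  # mean_a - mean_b
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def _per_patient_proportions(
    spectra: Mapping[str, SpectrumSummary], class_label: str
) -> np.ndarray:
    vals = [
        s.proportions[class_label]
        for s in spectra.values()
        if s.total > 0
    ]
    return np.asarray(vals, dtype=float)


def spectrum_shift_test(
    subset_a_spectra: Mapping[str, SpectrumSummary],
    subset_b_spectra: Mapping[str, SpectrumSummary],
    class_label: str,
    arcsine: bool = False,
) -> ShiftTestResult:
    """Test whether one class's per-patient proportion differs between subsets.

    ``arcsine`` applies the variance-stabilizing arcsine-square-root transform
    before the Welch t-test (proportions themselves are still reported on the
    raw scale).  Patients with empty subsets are excluded.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    a = _per_patient_proportions(subset_a_spectra, class_label)
    b = _per_patient_proportions(subset_b_spectra, class_label)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 patients with non-empty subsets per side")
    ta, tb = (np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))) if arcsine else (a, b)
    if np.allclose(ta, ta[0]) and np.allclose(tb, tb[0]) and np.isclose(ta[0], tb[0]):
        t_stat, p = 0.0, 1.0  # degenerate: identical constant groups
    else:
        t_stat, p = stats.ttest_ind(ta, tb, equal_var=False)
    return ShiftTestResult(
        class_label=class_label,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        effect=float(a.mean() - b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def spectrum_shift_anova(
    spectra_by_subset: Mapping[str, Mapping[str, SpectrumSummary]],
    class_label: str,
) -> tuple[float, float]:
    """One-way ANOVA of a class's per-patient proportions across >= 3 subsets."""
    groups = [
        _per_patient_proportions(spectra, class_label)
        for spectra in spectra_by_subset.values()
    ]
    if len(groups) < 3:
        raise ValueError("ANOVA requires >= 3 subsets; use spectrum_shift_test for 2")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pooled_spectrum_chisquare(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[float, float]:
    """Secondary diagnostic: chi-square on pooled class counts of two subsets."""
    table = np.array(
        [[counts_a.get(c, 0) for c in CLASSES], [counts_b.get(c, 0) for c in CLASSES]]
    )
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)


def cohort_spectrum_table(
    cohort_partitions: Mapping[str, "TrioPartition"],
    collapse: bool = True,
) -> pd.DataFrame:
    """Tidy patient x subset x class table of counts and proportions."""
    rows = []
    for pid, part in cohort_partitions.items():
        for subset_name in ("common", "unique_ptc", "unique_ant"):
            summ = spectrum(getattr(part, subset_name), collapse=collapse)
            for label, count in summ.counts.items():
                rows.append(
                    {
                        "patient_id": pid,
                        "subset": subset_name,
                        "class": label,
                        "count": count,
                        "proportion": summ.proportions.get(label, np.nan),
                    }
                )
    return pd.DataFrame(rows)
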