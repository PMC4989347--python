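"""Variant inclusion filters and the filter-robustness sweep.

Filters are applied in a fixed order — depth, then quality, then each named
exclusion set in turn — and a :class:`FilterReport` attributes each removed
variant to the first criterion that rejected it.  The retained set itself is
order-independent (every criterion is a per-variant predicate), so exclusion
sets commute; only the report's attribution depends on the documented order.

Variants lacking a depth or quality annotation pass those filters and are
tallied separately in the report, since annotation completeness varies
between call sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import partition as _partition
from . import spectra as _spectra
from .variant_io import Key, VariantSet


@dataclass
class FilterConfig:
    """Inclusion thresholds plus named known-variant exclusion sets.

    ``min_depth`` defaults to the 8x coverage floor used for exome inclusion;
    ``min_qual`` defaults to 0 (off) because "standard quality cut-offs" vary
    by caller.  ``exclusion_sets`` is an ordered list of (name, key set)
    pairs, e.g. a dbSNP-style catalog.
    """

    min_depth: int = 8
    min_qual: float = 0.0
    exclusion_sets: list[tuple[str, frozenset[Key]]] = field(default_factory=list)
    name: str = "default"

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        names = [n for n, _ in self.exclusion_sets]
        if len(names) != len(set(names)):
            raise ValueError("exclusion set names must be unique")


@dataclass
class FilterReport:
    """Counts removed per criterion, in application order depth -> qual -> exclusions."""

    n_input: int
    removed_depth: int
    removed_qual: int
    removed_exclusion: dict[str, int]
    n_missing_depth: int
    n_missing_qual: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": "depth", "removed": self.removed_depth},
            {"criterion": "qual", "removed": self.removed_qual},
        ]
        rows += [
            {"criterion": f"exclusion:{name}", "removed": n}
            for name, n in self.removed_exclusion.items()
        ]
        return pd.DataFrame(rows)


def apply_filters(vs: VariantSet, cfg: FilterConfig) -> tuple[VariantSet, FilterReport]:
    """Apply inclusion filters to one sample's signature.

    A variant is retained iff depth >= ``min_depth`` (or depth missing),
    qual >= ``min_qual`` (or qual missing), and its key is absent from every
    exclusion set.
    """
    retained = VariantSet(vs.sample_id, vs.tissue)
    removed_depth = removed_qual = 0
    removed_excl = {name: 0 for name, _ in cfg.exclusion_sets}
    missing_depth = missing_qual = 0
    for v in vs:
        if v.depth is None:
            missing_depth += 1
        elif v.depth < cfg.min_depth:
            removed_depth += 1
            continue
        if v.qual is None:
            missing_qual += 1
        elif v.qual < cfg.min_qual:
            removed_qual += 1
            continue
        excluded = False
        for name, keys in cfg.exclusion_sets:
            if v.key in keys:
                removed_excl[name] += 1
                excluded = True
                break
        if not excluded:
            retained.add(v)
    report = FilterReport(
        n_input=len(vs),
        removed_depth=removed_depth,
        removed_qual=removed_qual,
        removed_exclusion=removed_excl,
        n_missing_depth=missing_depth,
        n_missing_qual=missing_qual,
        n_retained=len(retained),
    )
    return retained, report


def filter_cohort(
    cohort: Mapping[str, Mapping[str, VariantSet]], cfg: FilterConfig
) -> dict[str, dict[str, VariantSet]]:
    """Apply one FilterConfig to every sample of a loaded cohort."""
    return {
        pid: {tissue: apply_filters(vs, cfg)[0] for tissue, vs in samples.items()}
        for pid, samples in cohort.items()
    }


def filter_sweep(
    cohort: Mapping[str, Mapping[str, VariantSet]],
    configs: Sequence[FilterConfig],
) -> pd.DataFrame:
    """Re-run the partition + spectrum pipeline under each filter configuration.

    Returns a tidy table (config x patient x subset x substitution class) of
    counts and proportions, for checking that spectral conclusions — e.g. the
    C>A enrichment of the late, tissue-unique subsets — are robust to the
    level of filtering.
    """
    if not configs:
        raise ValueError("need at least one FilterConfig")
    frames = []
    for cfg in configs:
        filtered = filter_cohort(cohort, cfg)
        parts = _partition.partition_cohort(filtered)
        table = _spectra.cohort_spectrum_table(parts)
        table.insert(0, "config", cfg.name)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
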