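"""Gene-level recurrence matrices and gene-set over-representation.

Given a gene list of interest (e.g. a KEGG MAPK export), the recurrence
matrix records, per gene and patient, in which evolutionary subsets that
patient carries at least one qualifying SNS — where "qualifying" is fixed to
the protein-altering consequences {nonsynonymous, stopgain, stoploss}.  Gene
assignment comes from each variant's annotation, not positional overlap.

Over-representation uses the one-sided hypergeometric tail (the probability
of observing at least as many hit genes in a pathway as seen, given the
background universe) with Benjamini-Hochberg correction across pathways.
"""

from __future__ import annotations

from pathlib import Path
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .partition import SUBSET_NAMES, TrioPartition

QUALIFYING_CONSEQUENCES = frozenset({"nonsynonymous", "stopgain", "stoploss"})


@dataclass
class RecurrenceResult:
    """Recurrence matrix plus the per-gene and per-subset summaries."""

    #: genes x patients; each cell a frozenset of subset labels
    matrix: pd.DataFrame
    #: per gene: number of patients with >= 1 qualifying variant anywhere
    per_gene_patients: pd.Series
    #: per subset: mean qualifying-variant count per patient
    per_subset_mean: pd.Series


def build_recurrence(
    cohort_partitions: Mapping[str, TrioPartition],
    gene_list: Sequence[str],
) -> RecurrenceResult:
    """Tabulate qualifying variants in the listed genes across the cohort.

    Genes absent from the cohort keep an (empty) row so the matrix always
    covers the supplied list.  The per-subset means count qualifying
    variants (not genes) among listed genes, averaged over patients.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValueError("gene list is empty")
    gene_set = set(genes)
    patients = list(cohort_partitions)
    cells: dict[str, dict[str, set]] = {g: {p: set() for p in patients} for g in genes}
    subset_counts = {p: dict.fromkeys(SUBSET_NAMES, 0) for p in patients}
    for pid, part in cohort_partitions.items():
        for subset_name in SUBSET_NAMES:
            for v in part.subset(subset_name):
                if v.consequence in QUALIFYING_CONSEQUENCES and v.gene in gene_set:
                    cells[v.gene][pid].add(subset_name)
                    subset_counts[pid][subset_name] += 1
    matrix = pd.DataFrame(
        {p: {g: frozenset(cells[g][p]) for g in genes} for p in patients}
    ).reindex(index=genes, columns=patients)
    per_gene = matrix.map(bool).sum(axis=1)
    per_subset = pd.DataFrame(subset_counts).T.mean(axis=0)
    per_subset.name = "mean_qualifying_per_patient"
    return RecurrenceResult(
        matrix=matrix,
        per_gene_patients=per_gene,
        per_subset_mean=per_subset.reindex(list(SUBSET_NAMES)),
    )


def overrepresentation_test(
    gene_hits: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    background: Iterable[str] | int,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH-FDR correction.

    ``gene_hits`` is the set of genes carrying qualifying variants;
    ``background`` the gene universe (a collection of symbols, or its size —
    in which case pathway sets are assumed pre-restricted to it).  Returns a
    table sorted by p with columns ``pathway, n_pathway, n_hits_in_pathway,
    p_value, q_value``.
    """
    hits = set(gene_hits)
    if isinstance(background, int):
        bg_size = background
        bg = None
    else:
        bg = set(background)
        bg_size = len(bg)
        if not hits <= bg:
            raise ValueError("gene hits must be a subset of the background universe")
    if len(hits) > bg_size:
        raise ValueError("more hits than background genes")
    rows = []
    for name, members in pathway_sets.items():
        pw = set(members)
        if bg is not None:
            pw &= bg
        if not pw:
            raise ValueError(f"pathway {name!r} is empty (after background restriction)")
        if len(pw) > bg_size:
            raise ValueError(f"pathway {name!r} larger than background")
        k = len(hits & pw)
        # P(X >= k), X ~ Hypergeom(M=bg_size, K=|pathway|, n=|hits|)
        p = float(stats.hypergeom.sf(k - 1, bg_size, len(pw), len(hits)))
        rows.append(
            {
                "pathway": name,
                "n_pathway": len(pw),
                "n_hits_in_pathway": k,
                "n_hits": len(hits),
                "n_background": bg_size,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values("p_value", ignore_index=True)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def recurrence_matrix_to_tsv(result: RecurrenceResult, path: str | Path) -> None:
    """Write the matrix with cells as comma-joined subset labels."""
    printable = result.matrix.map(lambda cell: ",".join(sorted(cell)))
    printable.to_csv(path, sep="\t", index_label="gene")
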