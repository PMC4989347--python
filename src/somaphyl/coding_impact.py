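"""Genetic-code degeneracy enumeration and a minimal CDS consequence caller.

The triplet code maps 64 codons onto 20 amino acids plus stop, and that
redundancy is unevenly distributed over substitution types: exhaustively
enumerating every (codon, position, alternate base) single-nucleotide change
— 64 x 3 x 3 = 576 events — and pooling the two strand-equivalent directed
types into each of the six collapsed classes (96 events per class) shows,
for example, that 33/96 = 34.4% of potential C>T changes are synonymous
versus only 19/96 = 19.8% of potential C>A changes.  A spectrum shifted from
C>T toward C>A is therefore intrinsically more likely to alter protein
sequence, before any selection acts.

Conventions fixed here and used everywhere: stop-to-stop is synonymous,
stop-involving changes stay in the denominator, and class pooling is
strand-collapsed.  The unpooled 48-event directed fractions are available
via ``pooled=False`` for transparency.

The consequence caller is intentionally minimal: it labels a variant against
a single transcript model (ordered CDS intervals on a strand) as
synonymous / nonsynonymous / stopgain / stoploss / noncoding, which is all
the downstream burden and recurrence summaries need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable
from scipy import stats

from .spectra import CLASSES, COMPLEMENT, classify_substitution
from .variant_io import Variant, VariantSet

CODING_CONSEQUENCES = ("synonymous", "nonsynonymous", "stopgain", "stoploss")

BASES = "ACGT"
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def standard_codon_map(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid (one-letter, '*' for stop) for an NCBI table id."""
    table = _BioCodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    if len(code) != 64:
        raise ValueError(f"codon table {table_id} does not cover all 64 codons")
    return code


def enumerate_codon_changes(codon_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Exhaustive 576-row table of single-nucleotide codon changes.

    Columns: ``codon``, ``position`` (1-3), ``ref_base``, ``alt_base``,
    ``alt_codon``, ``aa_ref``, ``aa_alt``, ``directed`` (e.g. ``G>A``),
    ``class_label`` (strand-collapsed), ``consequence``.
    """
    code = dict(codon_map) if codon_map is not None else standard_codon_map()
    rows = []
    for codon in CODONS:
        aa_ref = code[codon]
        for i in range(3):
            ref = codon[i]
            for alt in BASES:
                if alt == ref:
                    continue
                alt_codon = codon[:i] + alt + codon[i + 1 :]
                aa_alt = code[alt_codon]
                if aa_alt == aa_ref:
                    consequence = "synonymous"  # includes stop -> stop
                elif aa_alt == "*":
                    consequence = "stopgain"
                elif aa_ref == "*":
                    consequence = "stoploss"
                else:
                    consequence = "nonsynonymous"
                rows.append(
                    {
                        "codon": codon,
                        "position": i + 1,
                        "ref_base": ref,
                        "alt_base": alt,
                        "alt_codon": alt_codon,
                        "aa_ref": aa_ref,
                        "aa_alt": aa_alt,
                        "directed": f"{ref}>{alt}",
                        "class_label": classify_substitution(ref, alt),
                        "consequence": consequence,
                    }
                )
    return pd.DataFrame(rows)


def synonymous_fraction(
    cct: pd.DataFrame, class_label: str, pooled: bool = True
) -> float:
    """Fraction of a substitution class's potential codon changes that are synonymous.

    ``pooled=True`` uses the strand-collapsed class (96 events, e.g. C>T
    pooled with G>A); ``pooled=False`` treats ``class_label`` as a directed
    type (48 events, e.g. ``"G>A"``).
    """
    col = "class_label" if pooled else "directed"
    rows = cct[cct[col] == class_label]
    if rows.empty:
        raise ValueError(f"no rows for {class_label!r} in column {col}")
    return float((rows["consequence"] == "synonymous").mean())


def consequence_fractions(cct: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Per-class consequence fractions (rows: classes, columns: consequences)."""
    col = "class_label" if pooled else "directed"
    table = (
        cct.groupby(col)["consequence"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(CODING_CONSEQUENCES), fill_value=0.0)
    )
    table.index.name = "class"
    return table


@dataclass
class TranscriptModel:
    """A single protein-coding transcript: ordered CDS intervals on one strand.

    Intervals are 1-based fully closed genomic coordinates, sorted in genomic
    order and non-overlapping; their total length must be divisible by 3.
    """

    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds:
            raise ValueError(f"{self.transcript_id}: no CDS intervals")
        self.cds = sorted(self.cds)
        prev_end = 0
        for start, end in self.cds:
            if start > end or start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: CDS intervals must be sorted and non-overlapping"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    def genomic_positions(self) -> list[int]:
        """CDS positions in transcript (5'->3') order."""
        pos = [p for start, end in self.cds for p in range(start, end + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds)


def load_transcripts_gff3(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from the CDS features of a GFF3 file.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``ID``); the gene symbol is taken from ``gene_name``/``gene_id`` when
    present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", feat.attributes.get("ID", ["?"]))[0]
        g = groups.setdefault(
            parent,
            {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "cds": [],
                "gene": (
                    feat.attributes.get("gene_name", feat.attributes.get("gene_id", [None]))
                )[0],
            },
        )
        g["cds"].append((feat.start, feat.end))
    return [
        TranscriptModel(
            transcript_id=tid,
            chrom=g["chrom"],
            strand=g["strand"],
            cds=g["cds"],
            gene=g["gene"],
        )
        for tid, g in groups.items()
    ]


def write_transcripts_gff3(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    lines = ["##gff-version 3"]
    for tm in transcripts:
        attrs = f"ID={tm.transcript_id}"
        if tm.gene:
            attrs += f";gene_name={tm.gene}"
        lines.append(
            f"{tm.chrom}\tsomaphyl\tmRNA\t{tm.cds[0][0]}\t{tm.cds[-1][1]}\t.\t{tm.strand}\t.\t{attrs}"
        )
        for start, end in tm.cds:
            cds_attrs = f"ID=cds-{tm.transcript_id};Parent={tm.transcript_id}"
            if tm.gene:
                cds_attrs += f";gene_name={tm.gene}"
            lines.append(
                f"{tm.chrom}\tsomaphyl\tCDS\t{start}\t{end}\t.\t{tm.strand}\t0\t{cds_attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


class ReferenceMismatchError(ValueError):
    """Variant ref allele disagrees with the reference sequence."""


def call_consequence(
    v: Variant,
    tm: TranscriptModel,
    reference: str | Mapping[str, str],
    codon_map: Mapping[str, str] | None = None,
) -> str:
    """Label one variant against one transcript model.

    ``reference`` is the plus-strand genome sequence of ``tm.chrom`` (or a
    chrom -> sequence mapping).  The variant's ref allele must match the
    reference base at its locus.  Positions outside the CDS are ``noncoding``.
    """
    seq = reference[tm.chrom] if not isinstance(reference, str) else reference
    ref_base = seq[v.pos - 1].upper()
    if ref_base != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: variant ref {v.ref} != reference {ref_base}"
        )
    if v.chrom != tm.chrom or not tm.contains(v.pos):
        return "noncoding"
    code = dict(codon_map) if codon_map is not None else standard_codon_map()
    positions = tm.genomic_positions()
    idx = positions.index(v.pos)
    codon_idx, offset = divmod(idx, 3)
    codon_pos = positions[codon_idx * 3 : codon_idx * 3 + 3]
    bases = [seq[p - 1].upper() for p in codon_pos]
    alt = v.alt
    if tm.strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
        alt = COMPLEMENT[alt]
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
    aa_ref, aa_alt = code[ref_codon], code[alt_codon]
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def annotate_consequences(
    vs: VariantSet,
    transcripts: Sequence[TranscriptModel],
    reference: Mapping[str, str],
    codon_map: Mapping[str, str] | None = None,
) -> None:
    """Set ``consequence`` and ``gene`` in place for every variant of a set.

    Each variant is labelled against the first transcript whose CDS contains
    it; variants in no CDS become ``noncoding``.
    """
    code = dict(codon_map) if codon_map is not None else standard_codon_map()
    index = build_codon_index(transcripts)
    for v in vs:
        v.consequence, v.gene = consequence_from_index(
            index, reference, v.chrom, v.pos, v.ref, v.alt, code
        )


#: (chrom, pos) -> (transcript, genomic positions of the containing codon,
#: 0-based offset of this base within that codon, in transcript orientation)
CodonIndex = dict[tuple[str, int], tuple["TranscriptModel", tuple[int, ...], int]]


def build_codon_index(transcripts: Sequence[TranscriptModel]) -> CodonIndex:
    """Precompute, per CDS base, its transcript and containing codon."""
    index: CodonIndex = {}
    for tm in transcripts:
        positions = tm.genomic_positions()
        for i in range(0, len(positions), 3):
            codon_pos = tuple(positions[i : i + 3])
            for offset, p in enumerate(codon_pos):
                index.setdefault((tm.chrom, p), (tm, codon_pos, offset))
    return index


def consequence_from_index(
    index: CodonIndex,
    reference: Mapping[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    code: Mapping[str, str],
) -> tuple[str, str | None]:
    """(consequence, gene) for a substitution, via a prebuilt codon index."""
    hit = index.get((chrom, pos))
    if hit is None:
        return "noncoding", None
    tm, codon_pos, offset = hit
    seq = reference[tm.chrom]
    if seq[pos - 1].upper() != ref:
        raise ReferenceMismatchError(f"{chrom}:{pos}: variant ref {ref} != reference")
    bases = [seq[p - 1].upper() for p in codon_pos]
    if tm.strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
        alt = COMPLEMENT[alt]
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
    aa_ref, aa_alt = code[ref_codon], code[alt_codon]
    if aa_alt == aa_ref:
        return "synonymous", tm.gene
    if aa_alt == "*":
        return "stopgain", tm.gene
    if aa_ref == "*":
        return "stoploss", tm.gene
    return "nonsynonymous", tm.gene


NONSYN_CLASSES = frozenset({"nonsynonymous", "stopgain", "stoploss"})


@dataclass
class NonsynonymousSummary:
    """Per-patient/subset non-synonymous fractions with Welch contrasts."""

    fractions: pd.DataFrame  # patient x subset fraction of coding SNSs non-synonymous
    detail: pd.DataFrame  # tidy counts per consequence
    contrasts: dict[str, tuple[float, float]]  # subset -> (t, p) vs common


def nonsynonymous_fraction_by_subset(
    cohort_partitions: Mapping[str, "TrioPartition"],
) -> NonsynonymousSummary:
    """Fraction of coding SNSs that alter the protein, per patient and subset.

    Non-coding variants are excluded from the denominator; stopgain and
    stoploss count as non-synonymous (and are reported separately in the
    detail table).  Welch t contrasts each unique subset against Common
    across patients; patients lacking coding variants in a subset are
    excluded from that contrast.
    """
    rows = []
    for pid, part in cohort_partitions.items():
        for subset_name in ("common", "unique_ptc", "unique_ant"):
            counts = {c: 0 for c in CODING_CONSEQUENCES}
            for v in part.subset(subset_name):
                if v.consequence in counts:
                    counts[v.consequence] += 1
            n_coding = sum(counts.values())
            rows.append(
                {
                    "patient_id": pid,
                    "subset": subset_name,
                    "n_coding": n_coding,
                    **{f"n_{c}": n for c, n in counts.items()},
                    "nonsyn_fraction": (
                        sum(counts[c] for c in NONSYN_CLASSES) / n_coding
                        if n_coding
                        else np.nan
                    ),
                }
            )
    detail = pd.DataFrame(rows)
    fractions = detail.pivot(index="patient_id", columns="subset", values="nonsyn_fraction")
    contrasts = {}
    for subset_name in ("unique_ptc", "unique_ant"):
        paired = fractions[[subset_name, "common"]].dropna()
        if len(paired) >= 2:
            t, p = stats.ttest_ind(
                paired[subset_name], paired["common"], equal_var=False
            )
            contrasts[subset_name] = (float(t), float(p))
    return NonsynonymousSummary(fractions=fractions, detail=detail, contrasts=contrasts)
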