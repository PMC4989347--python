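"""Reading and writing the formats the pipeline touches.

The internal data model is deliberately small: a :class:`Variant` is one
single-nucleotide substitution (SNS) with optional evidence and annotations,
and a :class:`VariantSet` is the deduplicated SNS signature of one tissue
sample, keyed by ``(chrom, pos, ref, alt)``.  Genotype fields are ignored
throughout — presence of a record in a sample's call set means presence of
the SNS in that sample's signature.

Coordinates are 1-based and fully closed, following VCF.  Variant identity
performs no strand normalization; strand collapsing happens only when
spectra are computed (see :mod:`somaphyl.spectra`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml
from cyvcf2 import VCF

#: (chrom, pos, ref, alt) — the identity of an SNS throughout the package.
Key = tuple[str, int, str, str]

BASES = frozenset("ACGT")
TISSUES = ("PTC", "ANT", "BLOOD")
CONSEQUENCES = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "noncoding",
    "unknown",
)

N_PREDICTORS = 5  # protein-impact predictors feeding deleterious_votes


class VariantFormatError(ValueError):
    """Raised when an input file cannot be parsed into the data model."""


@dataclass
class Variant:
    """One single-nucleotide substitution.

    Parameters
    ----------
    chrom, pos, ref, alt
        Locus identity; ``pos`` is 1-based, ``ref``/``alt`` single bases.
    qual
        Variant quality score, if the caller provided one.
    depth
        Read depth at the site, if annotated.
    gene
        Gene symbol from annotation, if any.
    consequence
        Coding consequence; one of ``synonymous``, ``nonsynonymous``,
        ``stopgain``, ``stoploss``, ``noncoding``, ``unknown``.
    deleterious_votes
        Number of upstream protein-impact predictors (out of 5) that called
        the variant damaging.  Consumed, never computed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    depth: int | None = None
    gene: str | None = None
    consequence: str = "unknown"
    deleterious_votes: int | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise VariantFormatError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise VariantFormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise VariantFormatError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise VariantFormatError(f"unknown consequence {self.consequence!r}")
        if self.deleterious_votes is not None and not (
            0 <= self.deleterious_votes <= N_PREDICTORS
        ):
            raise VariantFormatError(
                f"deleterious_votes must be 0..{N_PREDICTORS}, got {self.deleterious_votes}"
            )

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """The deduplicated SNS signature of one tissue sample."""

    def __init__(self, sample_id: str, tissue: str, variants: Iterable[Variant] = ()):
        if tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
        self.sample_id = sample_id
        self.tissue = tissue
        self._variants: dict[Key, Variant] = {}
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        """Add a variant; a duplicate key silently keeps the first record."""
        self._variants.setdefault(v.key, v)

    def keys(self) -> set[Key]:
        return set(self._variants)

    def get(self, key: Key) -> Variant | None:
        return self._variants.get(key)

    def subset(self, keys: Iterable[Key], sample_id: str | None = None) -> "VariantSet":
        """New VariantSet restricted to ``keys`` (missing keys ignored)."""
        out = VariantSet(sample_id or self.sample_id, self.tissue)
        for k in keys:
            v = self._variants.get(k)
            if v is not None:
                out.add(v)
        return out

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants.values())

    def __contains__(self, key: Key) -> bool:
        return key in self._variants

    def __repr__(self) -> str:
        return f"VariantSet({self.sample_id!r}, {self.tissue}, n={len(self)})"


@dataclass
class PatientRecord:
    """One row of the cohort manifest: sample files plus grouping covariates."""

    patient_id: str
    ptc_path: str
    ant_path: str
    blood_path: str | None = None
    age: float | None = None
    sex: str | None = None
    race: str | None = None
    tnm_stage: str | None = None
    braf_mutant: bool | None = None
    histology: str | None = None


@dataclass
class CohortManifest:
    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids in manifest are not unique")

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


def read_variant_set(
    path: str | Path,
    sample_id: str,
    tissue: str,
    strip_chr: bool = False,
) -> VariantSet:
    """Read a VCF into a :class:`VariantSet` of biallelic SNSs.

    Multi-allelic records are decomposed (one variant per alternate base);
    indels and MNVs are counted and skipped; the result is deduplicated by
    key.  ``strip_chr`` removes a leading ``"chr"`` from chromosome names
    for dialect tolerance.
    """
    path = Path(path)
    vs = VariantSet(sample_id, tissue)
    n_records = n_skipped = 0
    try:
        reader = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VariantFormatError(f"cannot parse VCF {path}: {exc}") from exc
    try:
        for rec in reader:
            n_records += 1
            chrom = rec.CHROM
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            depth = rec.INFO.get("DP")
            if depth is not None:
                depth = int(depth)
            gene = rec.INFO.get("GENE")
            csq = rec.INFO.get("CSQ")
            votes = rec.INFO.get("VOTES")
            if votes is not None:
                votes = int(votes)
            for alt in rec.ALT:
                if len(rec.REF) != 1 or len(alt) != 1 or not (
                    rec.REF in BASES and alt in BASES
                ):
                    n_skipped += 1
                    continue
                vs.add(
                    Variant(
                        chrom=chrom,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        qual=rec.QUAL,
                        depth=depth,
                        gene=gene,
                        consequence=csq if csq in CONSEQUENCES else "unknown",
                        deleterious_votes=votes,
                    )
                )
    except Exception as exc:
        raise VariantFormatError(
            f"malformed VCF record near record {n_records + 1} in {path}: {exc}"
        ) from exc
    if n_records == 0:
        warnings.warn(f"{path}: empty VCF, returning empty VariantSet", stacklevel=2)
    return vs


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">',
    '##INFO=<ID=VOTES,Number=1,Type=Integer,Description="Deleterious predictor votes (0-5)">',
]


def write_variant_set(
    vs: VariantSet,
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write a VariantSet as a minimal VCF 4.2 file, sorted by locus.

    ``contigs`` (name -> length) adds ##contig header lines so downstream
    htslib-based readers stay quiet.
    """
    path = Path(path)
    lines = list(VCF_HEADER_LINES)
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(vs, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = []
        if v.depth is not None:
            info.append(f"DP={v.depth}")
        if v.gene is not None:
            info.append(f"GENE={v.gene}")
        if v.consequence != "unknown":
            info.append(f"CSQ={v.consequence}")
        if v.deleterious_votes is not None:
            info.append(f"VOTES={v.deleterious_votes}")
        qual = "." if v.qual is None else f"{v.qual:g}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t"
            + (";".join(info) if info else ".")
        )
    path.write_text("\n".join(lines) + "\n")


def _looks_like_vcf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            return line.startswith("##fileformat") or line.startswith("#CHROM")
    return False


def read_exclusion_list(path: str | Path) -> set[Key]:
    """Read a known-variant exclusion list (dbSNP-style) into a key set.

    Accepts either VCF or a headerless 4-column TSV (chrom, pos, ref, alt);
    positions 1-based in both dialects.
    """
    path = Path(path)
    keys: set[Key] = set()
    if _looks_like_vcf(path):
        vs = read_variant_set(path, sample_id="exclusion", tissue="BLOOD")
        return vs.keys()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise VariantFormatError(
                    f"{path}:{lineno}: expected 4 columns (chrom, pos, ref, alt)"
                )
            chrom, pos, ref, alt = parts[:4]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise VariantFormatError(f"{path}:{lineno}: bad position {pos!r}") from exc
            if ref not in BASES or alt not in BASES:
                raise VariantFormatError(
                    f"{path}:{lineno}: non-SNS record {ref!r}>{alt!r}"
                )
            keys.add((chrom, pos_i, ref, alt))
    return keys


def write_exclusion_list(keys: Iterable[Key], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(keys)
    path.write_text(
        "".join(f"{c}\t{p}\t{r}\t{a}\n" for c, p, r, a in rows)
    )


DAMAGING_CALLS = {"D", "1"}
TOLERATED_CALLS = {"T", "0", "", ".", "NA"}


def read_deleteriousness_table(path: str | Path) -> dict[Key, int]:
    """Read per-predictor damaging calls into a votes map.

    The table is TSV with columns ``chrom pos ref alt`` followed by up to
    five predictor columns holding ``D``/``T`` (or ``1``/``0``) calls.
    Votes = count of damaging calls; a missing call counts as non-damaging.
    """
    path = Path(path)
    votes: dict[Key, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise VariantFormatError(
                f"{path}: expected header starting chrom/pos/ref/alt, got {header[:4]}"
            )
        predictors = header[4:]
        if len(predictors) > N_PREDICTORS:
            raise VariantFormatError(
                f"{path}: {len(predictors)} predictor columns exceeds {N_PREDICTORS}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            chrom, pos, ref, alt = parts[:4]
            calls = parts[4 : 4 + len(predictors)]
            n = 0
            for call in calls:
                if call in DAMAGING_CALLS:
                    n += 1
                elif call not in TOLERATED_CALLS:
                    raise VariantFormatError(
                        f"{path}:{lineno}: unrecognized predictor call {call!r}"
                    )
            votes[(chrom, int(pos), ref, alt)] = n
    return votes


def write_deleteriousness_table(
    calls: Mapping[Key, Iterable[bool]],
    path: str | Path,
    predictor_names: Iterable[str] = ("polyphen2", "mutationtaster", "sift", "radialsvm", "lr"),
) -> None:
    """Write per-predictor boolean damaging calls as a votes TSV."""
    names = list(predictor_names)
    lines = ["\t".join(["chrom", "pos", "ref", "alt", *names])]
    for key in sorted(calls):
        c, p, r, a = key
        row = ["D" if flag else "T" for flag in calls[key]]
        if len(row) != len(names):
            raise ValueError(f"{key}: expected {len(names)} calls, got {len(row)}")
        lines.append("\t".join([c, str(p), r, a, *row]))
    Path(path).write_text("\n".join(lines) + "\n")


_MANIFEST_COLS = [f.name for f in fields(PatientRecord)]


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Read a cohort manifest from YAML (list of mappings) or TSV."""
    path = Path(path)
    rows: list[dict]
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, list):
            raise VariantFormatError(f"{path}: YAML manifest must be a list of mappings")
        rows = data
    else:
        import csv

        with open(path) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    patients = []
    for row in rows:
        kwargs = {k: row.get(k) for k in _MANIFEST_COLS if row.get(k) not in (None, "")}
        if "age" in kwargs:
            kwargs["age"] = float(kwargs["age"])
        if "braf_mutant" in kwargs and not isinstance(kwargs["braf_mutant"], bool):
            kwargs["braf_mutant"] = str(kwargs["braf_mutant"]).lower() in {"true", "1", "yes"}
        patients.append(PatientRecord(**kwargs))
    manifest = CohortManifest(patients)
    if check_paths:
        base = path.parent
        for p in manifest:
            for attr in ("ptc_path", "ant_path", "blood_path"):
                val = getattr(p, attr)
                if val is None:
                    continue
                f = Path(val)
                if not f.is_absolute():
                    f = base / f
                if not f.exists():
                    raise FileNotFoundError(f"manifest {attr} for {p.patient_id}: {f}")
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for p in manifest:
        row = {k: getattr(p, k) for k in _MANIFEST_COLS}
        rows.append({k: v for k, v in row.items() if v is not None})
    path.write_text(yaml.safe_dump(rows, sort_keys=False))


def load_cohort(
    manifest: CohortManifest | str | Path,
    strip_chr: bool = False,
) -> dict[str, dict[str, VariantSet]]:
    """Load every sample referenced by a manifest.

    Returns ``{patient_id: {"PTC": vs, "ANT": vs, "BLOOD": vs?}}``.  Paths
    are resolved relative to the manifest file when a path is given.
    """
    base = Path(".")
    if not isinstance(manifest, CohortManifest):
        base = Path(manifest).parent
        manifest = read_manifest(manifest)
    cohort: dict[str, dict[str, VariantSet]] = {}
    for p in manifest:
        samples: dict[str, VariantSet] = {}
        for tissue, attr in (("PTC", "ptc_path"), ("ANT", "ant_path"), ("BLOOD", "blood_path")):
            val = getattr(p, attr)
            if val is None:
                continue
            f = Path(val)
            if not f.is_absolute():
                f = base / f
            samples[tissue] = read_variant_set(
                f, sample_id=f"{p.patient_id}_{tissue}", tissue=tissue, strip_chr=strip_chr
            )
        cohort[p.patient_id] = samples
    return cohort
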