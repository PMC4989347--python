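"""Synthetic tumor-trio cohorts with the evolutionary structure the pipeline assumes.

The generator emulates a branching somatic-evolution model on a toy genome:

* a **germline** pool present in every tissue (the zygote's variants),
* an **early-shared** pool accrued before the hematopoietic/thyroid split
  (blood + tumor + adjacent normal),
* a **thyroid-shared** pool accrued between the blood split and the
  tumor/non-tumor divergence (tumor + adjacent normal only),
* **late** tissue-exclusive pools for tumor (PTC) and adjacent normal (ANT).

Pool sizes are Poisson; each variant's strand-collapsed substitution class
is drawn from the stage's spectrum (early pools C>T-dominant, late pools
C>A-enriched) and placed at a uniformly-chosen unused reference position
with a compatible base.  Consequences follow mechanically from placement on
the toy genome's CDS layout, and per-predictor deleteriousness calls are
sampled conditional on consequence — so every downstream quantity (shared
fractions, spectra, blood overlaps, non-synonymous and deleterious rates,
group burden offsets) has a closed-form expectation in the configuration,
which recovery tests exploit.

Identical configurations (including the seed) give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coding_impact, variant_io
from .coding_impact import TranscriptModel
from .spectra import CLASSES, COMPLEMENT
from .variant_io import (
    CohortManifest,
    Key,
    PatientRecord,
    Variant,
    VariantSet,
)

#: early (pre-divergence) spectrum: C>T transitions dominate, as in germline
#: polymorphism spectra shaped by 5-methylcytosine deamination
DEFAULT_EARLY_SPECTRUM = {
    "C>A": 0.05,
    "C>G": 0.05,
    "C>T": 0.65,
    "T>A": 0.05,
    "T>C": 0.15,
    "T>G": 0.05,
}

#: late (post-divergence, tissue-specific) spectrum: shifted toward C>A
#: transversions, the signature of oxidative (8-oxoguanine) damage
DEFAULT_LATE_SPECTRUM = {
    "C>A": 0.40,
    "C>G": 0.08,
    "C>T": 0.25,
    "T>A": 0.08,
    "T>C": 0.12,
    "T>G": 0.07,
}

STAGES = ("germline", "early_shared", "thyroid_shared", "late_ptc", "late_ant")

#: which tissues carry each stage's variants
STAGE_TISSUES = {
    "germline": ("PTC", "ANT", "BLOOD"),
    "early_shared": ("PTC", "ANT", "BLOOD"),
    "thyroid_shared": ("PTC", "ANT"),
    "late_ptc": ("PTC",),
    "late_ant": ("ANT",),
}


@dataclass
class SimConfig:
    """Cohort generator parameters.

    Pool-size means are per patient; the defaults give per-tumor totals,
    shared fractions and blood overlaps of the same order as a thyroid
    exome cohort (mean shared fraction ~0.76, blood/common overlap ~0.80).
    """

    n_patients: int = 20
    seed: int = 0
    n_germline: float = 3800.0
    n_early_shared: float = 600.0
    n_thyroid_shared: float = 1100.0
    n_late_ptc: float = 1700.0
    n_late_ant: float = 1700.0
    early_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EARLY_SPECTRUM)
    )
    late_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATE_SPECTRUM)
    )
    #: per-predictor probability of a damaging call, by consequence
    p_deleterious_given_nonsyn: float = 0.5
    p_deleterious_given_syn: float = 0.05
    #: added to the germline pool mean of BRAF-mutant patients (raises every
    #: tissue's totals, so tumor totals differ by the offset between groups)
    burden_offset_braf: float = 1000.0
    fraction_braf: float = 0.415
    #: fraction of germline-stage variants present in the known-variant
    #: catalog the cohort's exclusion list is built from (dbSNP-style)
    p_known_germline: float = 0.3
    mean_depth_tumor: float = 198.0
    mean_depth_normal: float = 95.0
    chrom: str = "chr1"
    chrom_length: int = 120_000
    n_transcripts: int = 30
    codons_per_transcript: int = 300

    def __post_init__(self) -> None:
        for name in ("early_spectrum", "late_spectrum"):
            probs = getattr(self, name)
            if set(probs) != set(CLASSES):
                raise ValueError(f"{name} must cover exactly the classes {CLASSES}")
            if not np.isclose(sum(probs.values()), 1.0):
                raise ValueError(f"{name} probabilities must sum to 1")
        for name in (
            "n_germline", "n_early_shared", "n_thyroid_shared",
            "n_late_ptc", "n_late_ant",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def stage_mean(self, stage: str, braf: bool) -> float:
        mean = {
            "germline": self.n_germline,
            "early_shared": self.n_early_shared,
            "thyroid_shared": self.n_thyroid_shared,
            "late_ptc": self.n_late_ptc,
            "late_ant": self.n_late_ant,
        }[stage]
        if stage == "germline" and braf:
            mean += self.burden_offset_braf
        return mean

    def stage_spectrum(self, stage: str) -> dict[str, float]:
        return self.late_spectrum if stage.startswith("late") else self.early_spectrum


@dataclass
class ToyGenome:
    """Random reference sequence plus a non-overlapping CDS layout."""

    sequences: dict[str, str]
    transcripts: list[TranscriptModel]

    def write(self, fasta_path: str | Path, gff3_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        coding_impact.write_transcripts_gff3(self.transcripts, gff3_path)


def make_toy_genome(cfg: SimConfig, rng: np.random.Generator) -> ToyGenome:
    """Uniform-random sequence with evenly spaced single-interval CDS genes."""
    seq = "".join(rng.choice(list("ACGT"), size=cfg.chrom_length))
    cds_len = cfg.codons_per_transcript * 3
    spacing = cfg.chrom_length // cfg.n_transcripts
    if cds_len + 10 > spacing:
        raise ValueError("toy genome too small for the requested transcript layout")
    transcripts = []
    for i in range(cfg.n_transcripts):
        start = i * spacing + 5  # 1-based
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{i + 1:03d}",
                chrom=cfg.chrom,
                strand="+" if i % 2 == 0 else "-",
                cds=[(start, start + cds_len - 1)],
                gene=f"GENE{i + 1:03d}",
            )
        )
    return ToyGenome(sequences={cfg.chrom: seq}, transcripts=transcripts)


@dataclass
class SimulatedPatient:
    patient_id: str
    braf_mutant: bool
    age: float
    sex: str
    race: str
    tnm_stage: str
    histology: str
    #: tissue -> VariantSet (PTC, ANT, BLOOD)
    samples: dict[str, VariantSet]
    #: per-variant stage labels: columns chrom, pos, ref, alt, stage
    truth: pd.DataFrame


@dataclass
class SimulatedCohort:
    config: SimConfig
    genome: ToyGenome
    patients: list[SimulatedPatient]
    #: cohort-wide known-variant catalog (germline-stage keys)
    exclusion_keys: set[Key]
    #: per-predictor damaging calls for every coding variant key
    predictor_calls: dict[Key, tuple[bool, ...]]

    @property
    def votes(self) -> dict[Key, int]:
        return {k: sum(calls) for k, calls in self.predictor_calls.items()}

    def as_cohort(self) -> dict[str, dict[str, VariantSet]]:
        """The in-memory shape :func:`somaphyl.variant_io.load_cohort` returns."""
        return {p.patient_id: dict(p.samples) for p in self.patients}

    def manifest(self, base: Path | None = None) -> CohortManifest:
        records = []
        for p in self.patients:
            prefix = "" if base is None else str(base) + "/"
            records.append(
                PatientRecord(
                    patient_id=p.patient_id,
                    ptc_path=f"{prefix}{p.patient_id}_PTC.vcf",
                    ant_path=f"{prefix}{p.patient_id}_ANT.vcf",
                    blood_path=f"{prefix}{p.patient_id}_BLOOD.vcf",
                    age=p.age,
                    sex=p.sex,
                    race=p.race,
                    tnm_stage=p.tnm_stage,
                    braf_mutant=p.braf_mutant,
                    histology=p.histology,
                )
            )
        return CohortManifest(records)

    def truth_table(self) -> pd.DataFrame:
        frames = []
        for p in self.patients:
            t = p.truth.copy()
            t.insert(0, "patient_id", p.patient_id)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def write(self, outdir: str | Path) -> Path:
        """Write the cohort in the exact formats :mod:`variant_io` reads.

        Emits per-sample VCFs, a YAML manifest, the exclusion list, the
        per-predictor votes table, the truth table, and the toy genome
        (FASTA + GFF3).  Returns the manifest path.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contigs = {name: len(seq) for name, seq in self.genome.sequences.items()}
        for p in self.patients:
            for tissue, vs in p.samples.items():
                variant_io.write_variant_set(
                    vs, outdir / f"{p.patient_id}_{tissue}.vcf", contigs=contigs
                )
        variant_io.write_manifest(self.manifest(), outdir / "manifest.yaml")
        variant_io.write_exclusion_list(self.exclusion_keys, outdir / "known_variants.tsv")
        variant_io.write_deleteriousness_table(
            self.predictor_calls, outdir / "deleteriousness.tsv"
        )
        self.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.genome.write(outdir / "genome.fa", outdir / "genes.gff3")
        return outdir / "manifest.yaml"


def _positions_by_strand_pair(sequence: str) -> dict[str, np.ndarray]:
    """1-based positions compatible with C-reference and T-reference classes."""
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    pos = np.arange(1, len(sequence) + 1)
    return {
        "C": pos[(arr == b"C") | (arr == b"G")],
        "T": pos[(arr == b"T") | (arr == b"A")],
    }


def _draw_variant_records(
    n: int,
    spectrum_probs: Mapping[str, float],
    positions: Mapping[str, np.ndarray],
    sequence: str,
    used: set[int],
    rng: np.random.Generator,
    chrom: str,
) -> list[tuple[str, int, str, str]]:
    """Place ``n`` substitutions at unused compatible loci.

    For class ``X>Y`` (pyrimidine reference X) a uniformly-drawn position
    carrying X yields ref X / alt Y; one carrying the complement of X yields
    the reverse-complemented directed substitution, so both strands are
    represented and the strand-collapsed class is exact by construction.
    """
    labels = list(CLASSES)
    probs = np.array([spectrum_probs[c] for c in labels])
    classes = rng.choice(len(labels), size=n, p=probs)
    out = []
    for ci in classes:
        pyr, alt_pyr = labels[ci].split(">")
        cands = positions[pyr]
        if len(used) >= len(cands):  # pragma: no cover - config guard
            raise RuntimeError(
                "toy genome exhausted; increase chrom_length in SimConfig"
            )
        while True:
            p = int(cands[rng.integers(len(cands))])
            if p not in used:
                break
        used.add(p)
        ref = sequence[p - 1]
        alt = alt_pyr if ref == pyr else COMPLEMENT[alt_pyr]
        out.append((chrom, p, ref, alt))
    return out


_RACES = (("C", 0.7), ("A", 0.1), ("H", 0.1), ("O", 0.1))
_STAGES_TNM = (("T1", 0.45), ("T2", 0.25), ("T3", 0.25), ("T4", 0.05))
_HISTOLOGY = (("classical", 0.7), ("follicular", 0.2), ("tall_cell", 0.1))


def _categorical(rng: np.random.Generator, table) -> str:
    labels, probs = zip(*table)
    return str(rng.choice(labels, p=np.array(probs)))


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full matched tumor/adjacent-normal/blood cohort.

    Every patient receives all three tissues.  Deterministic given the
    configuration: the same ``SimConfig`` (including ``seed``) always
    produces an identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = make_toy_genome(cfg, rng)
    sequence = genome.sequences[cfg.chrom]
    positions = _positions_by_strand_pair(sequence)
    codon_index = coding_impact.build_codon_index(genome.transcripts)
    code = coding_impact.standard_codon_map()

    patients: list[SimulatedPatient] = []
    exclusion_keys: set[Key] = set()
    coding_keys: dict[Key, str] = {}  # key -> consequence (first seen)

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        braf = bool(rng.random() < cfg.fraction_braf)
        age = float(np.clip(rng.normal(49.0, 15.0), 16.0, 97.0))
        sex = "F" if rng.random() < (2.5 / 3.5) else "M"
        race = _categorical(rng, _RACES)
        tnm = _categorical(rng, _STAGES_TNM)
        histology = _categorical(rng, _HISTOLOGY)

        used: set[int] = set()
        truth_rows = []
        tissue_variants: dict[str, list[Variant]] = {t: [] for t in ("PTC", "ANT", "BLOOD")}
        for stage in STAGES:
            n = int(rng.poisson(cfg.stage_mean(stage, braf)))
            records = _draw_variant_records(
                n, cfg.stage_spectrum(stage), positions, sequence, used, rng, cfg.chrom
            )
            for chrom, pos, ref, alt in records:
                key = (chrom, pos, ref, alt)
                csq, gene = coding_impact.consequence_from_index(
                    codon_index, genome.sequences, chrom, pos, ref, alt, code
                )
                if csq != "noncoding":
                    coding_keys.setdefault(key, csq)
                if stage == "germline" and rng.random() < cfg.p_known_germline:
                    exclusion_keys.add(key)
                truth_rows.append(
                    {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "stage": stage}
                )
                for tissue in STAGE_TISSUES[stage]:
                    mean_depth = (
                        cfg.mean_depth_tumor if tissue == "PTC" else cfg.mean_depth_normal
                    )
                    tissue_variants[tissue].append(
                        Variant(
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            qual=float(np.round(rng.uniform(30.0, 90.0), 1)),
                            depth=int(rng.poisson(mean_depth)),
                            gene=gene,
                            consequence=csq,
                        )
                    )
        samples = {
            tissue: VariantSet(f"{pid}_{tissue}", tissue, variants)
            for tissue, variants in tissue_variants.items()
        }
        patients.append(
            SimulatedPatient(
                patient_id=pid,
                braf_mutant=braf,
                age=age,
                sex=sex,
                race=race,
                tnm_stage=tnm,
                histology=histology,
                samples=samples,
                truth=pd.DataFrame(truth_rows),
            )
        )

    # one vote vector per coding key, shared cohort-wide so the votes table
    # is consistent across patients carrying the same variant
    predictor_calls: dict[Key, tuple[bool, ...]] = {}
    for key in sorted(coding_keys):
        p = (
            cfg.p_deleterious_given_nonsyn
            if coding_keys[key] in coding_impact.NONSYN_CLASSES
            else cfg.p_deleterious_given_syn
        )
        predictor_calls[key] = tuple(bool(b) for b in rng.random(5) < p)
    votes = {k: sum(c) for k, c in predictor_calls.items()}
    for patient in patients:
        for vs in patient.samples.values():
            for v in vs:
                if v.key in votes:
                    v.deleterious_votes = votes[v.key]

    return SimulatedCohort(
        config=cfg,
        genome=genome,
        patients=patients,
        exclusion_keys=exclusion_keys,
        predictor_calls=predictor_calls,
    )


def simulate_comparison_cohort(
    cfg: SimConfig, n_samples: int | None = None
) -> list[VariantSet]:
    """Blood-only germline-spectrum variant sets (an external comparison arm).

    Drawn on the same toy genome with the early spectrum and germline pool
    size only, from an independent stream derived from ``cfg.seed``; stands
    in for a population cohort of normal exomes.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    genome = make_toy_genome(cfg, np.random.default_rng(cfg.seed))
    sequence = genome.sequences[cfg.chrom]
    positions = _positions_by_strand_pair(sequence)
    codon_index = coding_impact.build_codon_index(genome.transcripts)
    code = coding_impact.standard_codon_map()
    n_samples = cfg.n_patients if n_samples is None else n_samples
    out = []
    for i in range(n_samples):
        sid = f"CMP{i + 1:03d}"
        used: set[int] = set()
        n = int(rng.poisson(cfg.n_germline))
        records = _draw_variant_records(
            n, cfg.early_spectrum, positions, sequence, used, rng, cfg.chrom
        )
        variants = []
        for chrom, pos, ref, alt in records:
            csq, gene = coding_impact.consequence_from_index(
                codon_index, genome.sequences, chrom, pos, ref, alt, code
            )
            votes = None
            if csq != "noncoding":
                p = (
                    cfg.p_deleterious_given_nonsyn
                    if csq in coding_impact.NONSYN_CLASSES
                    else cfg.p_deleterious_given_syn
                )
                votes = int(rng.binomial(5, p))
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=float(np.round(rng.uniform(30.0, 90.0), 1)),
                    depth=int(rng.poisson(cfg.mean_depth_normal)),
                    gene=gene,
                    consequence=csq,
                    deleterious_votes=votes,
                )
            )
        out.append(VariantSet(sid, "BLOOD", variants))
    return out


def scaled_config(cfg: SimConfig, factor: float) -> SimConfig:
    """A copy of ``cfg`` with every pool mean (and the BRAF offset) scaled."""
    return replace(
        cfg,
        n_germline=cfg.n_germline * factor,
        n_early_shared=cfg.n_early_shared * factor,
        n_thyroid_shared=cfg.n_thyroid_shared * factor,
        n_late_ptc=cfg.n_late_ptc * factor,
        n_late_ant=cfg.n_late_ant * factor,
        burden_offset_braf=cfg.burden_offset_braf * factor,
    )
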