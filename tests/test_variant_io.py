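"""I/O round-trips, VCF decomposition, and the dual-format exclusion list."""

from __future__ import annotations

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaphyl.variant_io import (
    Variant,
    VariantFormatError,
    VariantSet,
    read_deleteriousness_table,
    read_exclusion_list,
    read_manifest,
    read_variant_set,
    write_deleteriousness_table,
    write_exclusion_list,
    write_manifest,
    write_variant_set,
    CohortManifest,
    PatientRecord,
)

from conftest import make_set

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestVariant:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ref": "C", "alt": "C"},  # ref == alt
            {"ref": "N", "alt": "T"},  # non-ACGT
            {"pos": 0},  # 1-based coordinates
            {"deleterious_votes": 6},  # more votes than predictors
            {"consequence": "missense"},  # not in the vocabulary
        ],
    )
    def test_invalid_variants_rejected(self, kw):
        base = dict(chrom="1", pos=10, ref="C", alt="T")
        with pytest.raises((VariantFormatError, ValueError)):
            Variant(**{**base, **kw})

    def test_variantset_deduplicates_by_key(self):
        vs = make_set([("1", 1, "C", "T"), ("1", 1, "C", "T"), ("1", 2, "C", "T")])
        assert len(vs) == 2
        assert vs.keys() == {("1", 1, "C", "T"), ("1", 2, "C", "T")}


class TestReadVariantSet:
    def test_dedup_and_indel_skip(self, tmp_path):
        body = (
            "1\t100\t.\tC\tT\t50\t.\t.\n"
            "1\t100\t.\tC\tT\t50\t.\t.\n"
            "1\t200\t.\tG\tA\t50\t.\t.\n"
            "1\t300\t.\tCT\tC\t50\t.\t.\n"
        )
        vs = read_variant_set(write_vcf(tmp_path, body), "S", "PTC")
        assert vs.keys() == {("1", 100, "C", "T"), ("1", 200, "G", "A")}

    def test_multiallelic_decomposition(self, tmp_path):
        vs = read_variant_set(write_vcf(tmp_path, "1\t500\t.\tA\tC,G\t30\t.\t.\n"), "S", "PTC")
        assert vs.keys() == {("1", 500, "A", "C"), ("1", 500, "A", "G")}

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            vs = read_variant_set(write_vcf(tmp_path, ""), "S", "PTC")
        assert len(vs) == 0

    def test_malformed_file_is_fatal(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(VariantFormatError):
            read_variant_set(p, "S", "PTC")

    def test_strip_chr_prefix(self, tmp_path):
        vs = read_variant_set(
            write_vcf(tmp_path, "chr1\t100\t.\tC\tT\t50\t.\t.\n"), "S", "PTC", strip_chr=True
        )
        assert vs.keys() == {("1", 100, "C", "T")}

    def test_order_independence(self, tmp_path):
        lines = [
            "1\t100\t.\tC\tT\t50\t.\t.\n",
            "2\t50\t.\tG\tA\t40\t.\t.\n",
            "1\t700\t.\tT\tG\t60\t.\t.\n",
        ]
        a = read_variant_set(write_vcf(tmp_path, "".join(lines), "a.vcf"), "S", "PTC")
        b = read_variant_set(write_vcf(tmp_path, "".join(lines[::-1]), "b.vcf"), "S", "PTC")
        assert a.keys() == b.keys()


@st.composite
def variant_sets(draw):
    keys = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2"]),
                st.integers(1, 500),
                st.sampled_from("ACGT"),
                st.sampled_from("ACGT"),
            ).filter(lambda k: k[2] != k[3]),
            max_size=40,
        )
    )
    return make_set(keys, tissue="ANT")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(vs=variant_sets())
def test_vcf_round_trip_preserves_keys(tmp_path_factory, vs):
    """read(write(X)) preserves the variant key set for any VariantSet."""
    d = tmp_path_factory.mktemp("rt")
    path = d / "rt.vcf"
    write_variant_set(vs, path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        back = read_variant_set(path, vs.sample_id, vs.tissue)
    assert back.keys() == vs.keys()


class TestExclusionList:
    def test_tsv_with_duplicate_rows(self, tmp_path):
        p = tmp_path / "ex.tsv"
        p.write_text("1\t10\tC\tT\n1\t10\tC\tT\n2\t20\tG\tA\n")
        assert read_exclusion_list(p) == {("1", 10, "C", "T"), ("2", 20, "G", "A")}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ex.tsv"
        p.write_text("")
        assert read_exclusion_list(p) == set()

    def test_vcf_dialect_equals_tsv_dialect(self, tmp_path):
        keys = {("1", 10, "C", "T"), ("2", 20, "G", "A"), ("2", 21, "T", "G")}
        tsv = tmp_path / "ex.tsv"
        write_exclusion_list(keys, tsv)
        vcf = write_vcf(
            tmp_path,
            "".join(f"{c}\t{p}\t.\t{r}\t{a}\t.\t.\t.\n" for c, p, r, a in sorted(keys)),
            "ex.vcf",
        )
        assert read_exclusion_list(tsv) == read_exclusion_list(vcf) == keys

    def test_unknown_format_is_fatal(self, tmp_path):
        p = tmp_path / "ex.tsv"
        p.write_text("1,10,C,T\n")
        with pytest.raises(VariantFormatError):
            read_exclusion_list(p)


class TestDeleteriousnessTable:
    HEADER = "chrom\tpos\tref\talt\tp1\tp2\tp3\tp4\tp5\n"

    def test_vote_counting(self, tmp_path):
        p = tmp_path / "del.tsv"
        p.write_text(self.HEADER + "1\t10\tC\tT\tD\tD\tT\tD\tT\n1\t20\tG\tA\tT\tT\tT\tT\tT\n")
        votes = read_deleteriousness_table(p)
        assert votes[("1", 10, "C", "T")] == 3
        assert votes[("1", 20, "G", "A")] == 0

    def test_missing_predictor_counts_as_tolerated(self, tmp_path):
        p = tmp_path / "del.tsv"
        p.write_text("chrom\tpos\tref\talt\tp1\tp2\n1\t10\tC\tT\tD\t\n")
        assert read_deleteriousness_table(p)[("1", 10, "C", "T")] == 1

    def test_too_many_predictor_columns_fatal(self, tmp_path):
        p = tmp_path / "del.tsv"
        cols = "\t".join(f"p{i}" for i in range(6))
        p.write_text(f"chrom\tpos\tref\talt\t{cols}\n")
        with pytest.raises(VariantFormatError):
            read_deleteriousness_table(p)

    def test_round_trip(self, tmp_path):
        calls = {
            ("1", 10, "C", "T"): (True, False, True, False, False),
            ("2", 5, "G", "A"): (False,) * 5,
        }
        p = tmp_path / "del.tsv"
        write_deleteriousness_table(calls, p)
        assert read_deleteriousness_table(p) == {k: sum(v) for k, v in calls.items()}


class TestManifest:
    def test_yaml_round_trip(self, tmp_path):
        manifest = CohortManifest(
            [
                PatientRecord(
                    patient_id="P1",
                    ptc_path="p1_ptc.vcf",
                    ant_path="p1_ant.vcf",
                    age=51.0,
                    sex="F",
                    braf_mutant=True,
                )
            ]
        )
        path = tmp_path / "m.yaml"
        write_manifest(manifest, path)
        back = read_manifest(path, check_paths=False)
        assert back.patients[0] == manifest.patients[0]

    def test_duplicate_patient_ids_rejected(self):
        rec = PatientRecord(patient_id="P1", ptc_path="a", ant_path="b")
        with pytest.raises(ValueError, match="unique"):
            CohortManifest([rec, rec])

    def test_missing_paths_detected(self, tmp_path):
        path = tmp_path / "m.yaml"
        write_manifest(
            CohortManifest([PatientRecord(patient_id="P1", ptc_path="no.vcf", ant_path="no.vcf")]),
            path,
        )
        with pytest.raises(FileNotFoundError):
            read_manifest(path, check_paths=True)
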