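"""Domain types, identifiers, pre-QC normalization, intervals, and VCF I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliqc import (
    AlleleClass,
    ClinVarEntry,
    IntervalSet,
    TriallelicSubtype,
    VariantSite,
    classify_allele,
    classify_triallelic_subtype,
    gatk_pass_prefilter,
    make_cpra,
    match_clinvar,
    overlaps_interval,
    partition_by_allele_count,
    read_vcf,
    remove_monomorphic,
    split_triallelic,
    write_vcf,
)
from repliqc.errors import (
    AmbiguousClinVarError,
    ContractError,
    InvalidRecordError,
    UnsupportedSubtypeError,
)

from conftest import make_dataset, snv


class TestCpra:
    @pytest.mark.parametrize(
        "args, expected",
        [
            (("2", 100, "A", "G"), "2.100.A.G"),
            (("7", 117199644, "CTT", "C"), "7.117199644.CTT.C"),
        ],
    )
    def test_format(self, args, expected):
        assert make_cpra(*args) == expected

    def test_distinct_alts_give_distinct_ids(self):
        assert make_cpra("2", 100, "A", "G") != make_cpra("2", 100, "A", "T")

    @pytest.mark.parametrize("bad", [("", 1, "A", "G"), ("1", 1, "", "G"), ("1", 0, "A", "G")])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidRecordError):
            make_cpra(*bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.tuples(
            st.sampled_from(["1", "2", "X"]),
            st.integers(1, 10**6),
            st.text("ACGT", min_size=1, max_size=4),
            st.text("ACGT", min_size=1, max_size=4),
        ),
        st.tuples(
            st.sampled_from(["1", "2", "X"]),
            st.integers(1, 10**6),
            st.text("ACGT", min_size=1, max_size=4),
            st.text("ACGT", min_size=1, max_size=4),
        ),
    )
    def test_injective_on_distinct_inputs(self, a, b):
        # dot-joined fields over a dot-free alphabet are uniquely decodable
        if a != b:
            assert make_cpra(*a) != make_cpra(*b)


class TestAlleleClassification:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "G", AlleleClass.SNV),
            ("A", "AT", AlleleClass.INDEL),
            ("ATTT", "A", AlleleClass.INDEL),
            ("AT", "*", AlleleClass.SYMBOLIC),
            ("A", "<DEL>", AlleleClass.SYMBOLIC),
        ],
    )
    def test_classify(self, ref, alt, expected):
        assert classify_allele(ref, alt) is expected

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(InvalidRecordError):
            classify_allele("A", "A")

    @pytest.mark.parametrize(
        "ref, alt1, alt2, expected",
        [
            ("A", "G", "T", TriallelicSubtype.SNV_SNV),
            ("A", "G", "AT", TriallelicSubtype.SNV_INDEL),
            ("A", "AT", "ATT", TriallelicSubtype.INDEL_INDEL),
            ("AT", "A", "*", TriallelicSubtype.OTHER_INDEL),
        ],
    )
    def test_triallelic_subtype(self, ref, alt1, alt2, expected):
        assert classify_triallelic_subtype(ref, alt1, alt2) is expected
        assert classify_triallelic_subtype(ref, alt2, alt1) is expected  # unordered

    def test_two_symbolic_alts_unsupported(self):
        with pytest.raises(UnsupportedSubtypeError):
            classify_triallelic_subtype("AT", "*", "<DEL>")


class TestPartitionAndSplit:
    def test_partition(self):
        sites = [
            snv(100),
            VariantSite(chrom="1", pos=200, ref="A", alts=("G", "T")),
        ]

        class Raw:  # >= 3 alts never becomes a VariantSite; partition sees raw records
            alts = ("G", "T", "C")

        parts = partition_by_allele_count(sites + [Raw()])
        assert parts["biallelic"] == [0]
        assert parts["triallelic"] == [1]
        assert parts["excluded"] == [(2, ">=4 alleles")]

    def test_split_shares_annotations_and_differs_in_cpra(self):
        parent = VariantSite(
            chrom="1", pos=500, ref="A", alts=("G", "T"), mq=59.5, dp_total=7000.0
        )
        row1, row2 = split_triallelic(parent)
        assert (row1.mq, row1.dp_total) == (row2.mq, row2.dp_total) == (59.5, 7000.0)
        assert row1.cpras != row2.cpras
        # subtype recoverable from the split rows' allele classes
        assert classify_triallelic_subtype(parent.ref, row1.alts[0], row2.alts[0]) is parent.subtype

    def test_split_rejects_biallelic(self):
        with pytest.raises(ContractError):
            split_triallelic(snv())

    def test_subtype_present_iff_two_alts(self):
        assert snv().subtype is None
        assert VariantSite(chrom="1", pos=1, ref="A", alts=("G", "T")).subtype is not None


class TestPreFilters:
    def _dataset(self):
        sites = [
            snv(100, filter_status="PASS"),
            snv(200, filter_status="VQSRTrancheSNP99.80to100.00"),
            snv(300, filter_status="PASS"),
            snv(400, filter_status="PASS"),
        ]
        gt = [
            [(0, 1), (0, 0)],  # polymorphic
            [(0, 1), (1, 1)],  # polymorphic but tranche
            [(0, 0), (0, 0)],  # monomorphic
            [(-1, -1), (-1, -1)],  # all missing -> monomorphic
        ]
        return make_dataset(sites, gt)

    def test_pass_prefilter(self):
        ds = self._dataset()
        assert list(gatk_pass_prefilter(ds)) == [0, 2, 3]

    def test_monomorphic_removal_including_all_missing(self):
        ds = self._dataset()
        assert list(remove_monomorphic(ds)) == [0, 1]

    def test_one_het_retains_site(self):
        ds = make_dataset([snv()], [[(0, 1), (0, 0), (0, 0)]])
        assert list(remove_monomorphic(ds)) == [0]

    def test_prefilter_order_stable(self):
        ds = self._dataset()
        a = remove_monomorphic(ds, gatk_pass_prefilter(ds))
        b = gatk_pass_prefilter(ds, remove_monomorphic(ds))
        assert list(a) == list(b) == [0]


class TestClinVarMatching:
    def _entries(self):
        return [
            ClinVarEntry(cpra="1.100.A.G", rsid="rs1", star_level=2),
            ClinVarEntry(cpra="1.500.A.T", rsid="rs2", star_level=3),
        ]

    def test_biallelic_match_and_drop(self):
        ds = make_dataset([snv(100), snv(300)], [[(0, 1)], [(0, 1)]])
        retained, annot = match_clinvar(ds, self._entries())
        assert list(retained) == [0]
        assert annot[0].rsid == "rs1"

    def test_triallelic_matches_on_either_split_row(self):
        tri = VariantSite(chrom="1", pos=500, ref="A", alts=("G", "T"))
        ds = make_dataset([tri], [[(1, 2)]])
        retained, annot = match_clinvar(ds, self._entries())
        assert list(retained) == [0]
        assert annot[0].rsid == "rs2"  # annotated from the matching allele row

    def test_duplicate_cpra_is_ambiguous(self):
        dup = self._entries() + [ClinVarEntry(cpra="1.100.A.G", rsid="rs9", star_level=0)]
        ds = make_dataset([snv(100)], [[(0, 1)]])
        with pytest.raises(AmbiguousClinVarError) as exc:
            match_clinvar(ds, dup)
        assert "1.100.A.G" in str(exc.value)


class TestIntervals:
    def test_bed_coordinate_conversion(self):
        iset = IntervalSet([("chr1", 99, 100)])
        assert overlaps_interval(snv(100), iset)  # BED [99,100) is 1-based pos 100
        assert not overlaps_interval(snv(101), iset)

    def test_deletion_span_overlaps(self):
        iset = IntervalSet([("chr1", 99, 100)])
        site = VariantSite(chrom="1", pos=98, ref="ATTT", alts=("A",))
        assert overlaps_interval(site, iset)

    def test_chromosome_dialects_normalized(self):
        iset = IntervalSet([("chr2", 0, 10)])
        assert overlaps_interval(snv(5, chrom="2"), iset)

    def test_unknown_chromosome_returns_false(self):
        iset = IntervalSet([("1", 0, 10)])
        assert not overlaps_interval(snv(5, chrom="9"), iset)

    def test_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pos = int(rng.integers(1, 300))
            ref_len = int(rng.integers(1, 5))
            start = int(rng.integers(0, 300))
            end = start + int(rng.integers(1, 30))
            site = VariantSite(chrom="1", pos=pos, ref="A" * ref_len, alts=("A" * ref_len + "T",))
            iset = IntervalSet([("1", start, end)])
            # brute force: does any 1-based reference base fall inside the interval?
            covered = {b for b in range(start + 1, end + 1)}  # 1-based bases of [start, end)
            oracle = any(p in covered for p in range(pos, pos + ref_len))
            assert overlaps_interval(site, iset) == oracle


class TestVcfRoundTrip:
    def test_write_then_read_preserves_cpra_and_annotations(self, cohort, tmp_path):
        _, dataset, _ = cohort
        sub = dataset.subset(np.arange(300))
        path = tmp_path / "out.vcf"
        write_vcf(sub, path)
        back = read_vcf(path)
        assert [s.cpras for s in back.sites] == [s.cpras for s in sub.sites]
        assert back.sites == sub.sites  # annotations, FILTER, alleles all equal
        assert np.array_equal(back.gt, sub.gt)
        assert np.array_equal(back.dp, sub.dp)
        assert np.array_equal(back.gq, sub.gq)

    def test_allele_count_reconciliation(self, cohort):
        _, dataset, _ = cohort
        parts = partition_by_allele_count(dataset.sites)
        total = len(parts["biallelic"]) + len(parts["triallelic"]) + len(parts["excluded"])
        assert total == dataset.n_sites
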