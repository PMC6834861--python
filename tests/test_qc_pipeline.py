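"""Nine-filter engine: boundary semantics, sequential/independent modes."""

import numpy as np
import pytest

from repliqc import (
    IntervalSet,
    ThresholdSpec,
    VariantSite,
    genotype_mask,
    run_independent,
    run_sequential,
    sample_missingness_filter,
    variant_missingness,
    variant_pass_mask,
)
from repliqc.errors import ContractError
from repliqc.qc_pipeline import VARIANT_FILTERS, sample_missingness

from conftest import make_dataset, snv

NOOP = ThresholdSpec(
    variant_missingness_max=1.1,
    site_dp_min=-1e30,
    mq_lo=-1e30,
    mq_hi=1e30,
    vqslod_min=-1e30,
    inbreeding_min=-2.0,
    gt_dp_min=0,
    gt_gq_min=0,
    sample_missingness_max=1.1,
)


class TestThresholdSpec:
    def test_defaults_are_reference_values(self):
        t = ThresholdSpec()
        assert (t.variant_missingness_max, t.site_dp_min) == (0.05, 25_000)
        assert (t.mq_lo, t.mq_hi, t.vqslod_min) == (58.75, 61.25, 7.81)
        assert (t.inbreeding_min, t.gt_dp_min, t.gt_gq_min) == (-0.8, 10, 20)
        assert t.sample_missingness_max == 0.10

    def test_yaml_round_trip_and_partial_file(self, tmp_path):
        path = tmp_path / "t.yaml"
        ThresholdSpec(vqslod_min=3.0).to_yaml(path)
        assert ThresholdSpec.from_yaml(path) == ThresholdSpec(vqslod_min=3.0)
        (tmp_path / "partial.yaml").write_text("site_dp_min: 900\n")
        partial = ThresholdSpec.from_yaml(tmp_path / "partial.yaml")
        assert partial.site_dp_min == 900 and partial.mq_lo == 58.75

    def test_invalid_specs_rejected(self):
        with pytest.raises(ContractError):
            ThresholdSpec(mq_lo=62.0, mq_hi=60.0)
        with pytest.raises(ContractError):
            ThresholdSpec(filter_order=("mq", "mq", "site_dp", "vqslod", "inbreeding", "missingness"))


class TestSiteFilterBoundaries:
    """Annotation filters remove on strict inequality: the threshold value passes."""

    def _mask(self, site, fid, **spec_kw):
        ds = make_dataset([site], [[(0, 1)]])
        return variant_pass_mask(ds, fid, ThresholdSpec(**spec_kw))[0]

    @pytest.mark.parametrize(
        "dp, passes", [(25_000.0, True), (24_999.0, False), (25_001.0, True)]
    )
    def test_site_dp(self, dp, passes):
        assert self._mask(snv(dp_total=dp), "site_dp") == passes

    @pytest.mark.parametrize(
        "mq, passes",
        [(58.75, True), (61.25, True), (58.74, False), (61.26, False), (60.0, True)],
    )
    def test_mq_window(self, mq, passes):
        assert self._mask(snv(mq=mq), "mq") == passes

    @pytest.mark.parametrize("v, passes", [(7.81, True), (7.80, False), (9.0, True)])
    def test_vqslod_snv(self, v, passes):
        assert self._mask(snv(vqslod=v), "vqslod") == passes

    def test_vqslod_skips_non_snv_sites(self):
        indel = VariantSite(chrom="1", pos=10, ref="A", alts=("AT",), vqslod=2.0)
        assert self._mask(indel, "vqslod")
        tri_mixed = VariantSite(chrom="1", pos=10, ref="A", alts=("G", "AT"), vqslod=2.0)
        assert self._mask(tri_mixed, "vqslod")
        tri_snv = VariantSite(chrom="1", pos=10, ref="A", alts=("G", "T"), vqslod=2.0)
        assert not self._mask(tri_snv, "vqslod")

    @pytest.mark.parametrize("f, passes", [(-0.8, True), (-0.81, False), (0.2, True)])
    def test_inbreeding(self, f, passes):
        assert self._mask(snv(inbreeding_coeff=f), "inbreeding") == passes

    def test_absent_annotation_fails_open_and_strict_flips(self):
        bare = snv()  # no annotations at all
        ds = make_dataset([bare], [[(0, 1)]])
        for fid in ("site_dp", "mq", "vqslod", "inbreeding"):
            assert variant_pass_mask(ds, fid, ThresholdSpec())[0]
            assert not variant_pass_mask(ds, fid, ThresholdSpec(), strict=True)[0]


class TestMissingnessBoundaries:
    """Missingness filters remove on >= their cutoff (boundary fails)."""

    def test_variant_missingness_fractions(self):
        gt_rows = [[(0, 1)] * 259, [(0, 1)] * 246 + [(-1, -1)] * 13]
        ds = make_dataset([snv(100), snv(200)], gt_rows)
        fracs = variant_missingness(ds)
        assert fracs[0] == 0.0
        assert fracs[1] == pytest.approx(13 / 259)
        passed = variant_pass_mask(ds, "missingness", ThresholdSpec())
        assert list(passed) == [True, False]  # 5.02% >= 5% -> removed

    def test_exact_five_percent_removed(self):
        gt = [[(0, 1)] * 19 + [(-1, -1)]]  # 1/20 = exactly 5%
        ds = make_dataset([snv()], gt)
        assert not variant_pass_mask(ds, "missingness", ThresholdSpec())[0]

    def test_sample_boundary_ten_percent(self):
        n_sites = 10
        gt = [[(0, 1), (0, 1)] for _ in range(n_sites)]
        gt[0][1] = (-1, -1)  # sample P1 missing 1/10 = 10%
        ds = make_dataset([snv(100 + i) for i in range(n_sites)], gt)
        assert sample_missingness(ds)[1] == pytest.approx(0.10)
        assert sample_missingness_filter(ds, ThresholdSpec()) == ["P1"]

    def test_below_boundary_retained(self):
        gt = [[(0, 1), (0, 1)] for _ in range(20)]
        gt[0][1] = (-1, -1)  # 1/20 = 5% < 10%
        ds = make_dataset([snv(100 + i) for i in range(20)], gt)
        assert sample_missingness_filter(ds, ThresholdSpec()) == []


class TestGenotypeFilters:
    @pytest.mark.parametrize(
        "dp, gq, masked",
        [(9, 99, True), (10, 20, False), (30, 19, True), (10, 99, False), (9, 19, True)],
    )
    def test_boundaries(self, dp, gq, masked):
        ds = make_dataset([snv()], [[(0, 1)]], dp=[[dp]], gq=[[gq]])
        assert genotype_mask(ds, ThresholdSpec())[0, 0] == masked

    def test_masking_preserves_original_call_for_audit(self):
        ds = make_dataset([snv()], [[(1, 1)]], dp=[[5]], gq=[[99]])
        ds.masked |= genotype_mask(ds, ThresholdSpec())
        call = ds.genotype(0, 0)
        assert call.masked and call.alleles == (1, 1)
        assert call.effective_alleles is None  # downstream sees MISSING

    def test_absent_format_key_passes(self):
        ds = make_dataset([snv()], [[(0, 1)]], dp=[[-1]], gq=[[-1]])
        assert not genotype_mask(ds, ThresholdSpec())[0, 0]


def brute_force_sequential_counts(ds, idx, spec, order, interval_sets=()):
    """Row-by-row re-evaluation of the variant-level predicates, in order."""
    current = list(idx)
    counts = []
    for fid in order:
        kept = []
        for i in current:
            s = ds.sites[i]
            if fid == "missingness":
                frac = float(np.mean(ds.gt[i, :, 0] < 0))
                ok = frac < spec.variant_missingness_max
            elif fid == "blacklist_lcr":
                from repliqc import overlaps_interval

                ok = not any(overlaps_interval(s, iv) for iv in interval_sets)
            elif fid == "site_dp":
                ok = s.dp_total is None or s.dp_total >= spec.site_dp_min
            elif fid == "mq":
                ok = s.mq is None or spec.mq_lo <= s.mq <= spec.mq_hi
            elif fid == "inbreeding":
                ok = s.inbreeding_coeff is None or s.inbreeding_coeff >= spec.inbreeding_min
            elif fid == "vqslod":
                ok = (
                    not s.vqslod_eligible
                    or s.vqslod is None
                    or s.vqslod >= spec.vqslod_min
                )
            if ok:
                kept.append(i)
        counts.append(len(kept))
        current = kept
    return counts, current


class TestRunSequential:
    def _spec(self):
        # thresholds sized to the synthetic cohort's annotation scales
        return ThresholdSpec(site_dp_min=550.0, mq_lo=59.0, mq_hi=61.0, vqslod_min=3.0)

    def test_stage_counts_match_brute_force(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        spec = self._spec()
        trace, final = run_sequential(ds, spec, site_indices=biallelic_indices)
        oracle_counts, oracle_final = brute_force_sequential_counts(
            ds, biallelic_indices, spec, spec.filter_order
        )
        variant_records = trace.records[1:7]
        assert [r.n_pass for r in variant_records] == oracle_counts
        assert [s.cpras for s in final.sites] == [ds.sites[i].cpras for i in oracle_final]

    def test_noop_thresholds_identity(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        trace, final = run_sequential(ds, NOOP, site_indices=biallelic_indices)
        assert all(r.pct_pass == 100.0 for r in trace.records)
        assert final.n_sites == len(biallelic_indices)
        assert not final.masked.any()
        assert final.n_samples == ds.n_samples

    def test_variant_order_invariance(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        spec = self._spec()
        orders = [
            VARIANT_FILTERS,
            ("vqslod", "inbreeding", "mq", "site_dp", "blacklist_lcr", "missingness"),
        ]
        finals = [
            run_sequential(ds, spec, site_indices=biallelic_indices, order=o)[1]
            for o in orders
        ]
        assert [s.cpras for s in finals[0].sites] == [s.cpras for s in finals[1].sites]

    def test_pass_counts_non_increasing_and_provenance_unique(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        spec = self._spec()
        trace, final = run_sequential(ds, spec, site_indices=biallelic_indices)
        variant_counts = [r.n_pass for r in trace.records[:7]]
        assert all(a >= b for a, b in zip(variant_counts, variant_counts[1:]))
        # every removed site has exactly one first-removing stage
        removed = set(biallelic_indices) - {
            i for i in biallelic_indices if ds.sites[i].cpras in {s.cpras for s in final.sites}
        }
        assert set(trace.removed_by) == removed


class TestRunIndependent:
    def test_noop_removes_nothing(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        outcomes = run_independent(ds, NOOP, site_indices=biallelic_indices)
        for fid in VARIANT_FILTERS:
            assert outcomes[fid].n_removed == 0

    def test_union_equals_sequential_complement(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        spec = ThresholdSpec(site_dp_min=550.0, mq_lo=59.0, mq_hi=61.0, vqslod_min=3.0)
        trace, _ = run_sequential(ds, spec, site_indices=biallelic_indices)
        outcomes = run_independent(ds, spec, site_indices=biallelic_indices)
        union = set()
        for fid in VARIANT_FILTERS:
            union |= set(outcomes[fid].removed_ids)
        assert union == set(trace.removed_by)

    def test_only_varying_filter_fires(self):
        sites = [
            snv(100 + i, dp_total=float(dp), mq=60.0, vqslod=50.0, inbreeding_coeff=0.0)
            for i, dp in enumerate([30_000, 20_000, 26_000, 10_000])
        ]
        ds = make_dataset(sites, [[(0, 1), (1, 1)]] * 4, pairs=[("P0", "P1")])
        outcomes = run_independent(ds, ThresholdSpec())
        assert set(outcomes["site_dp"].removed_ids) == {1, 3}
        for fid in set(VARIANT_FILTERS) - {"site_dp"}:
            assert outcomes[fid].n_removed == 0

    def test_confusion_partitions_pair_observations(self, cohort, biallelic_indices):
        _, ds, _ = cohort
        spec = ThresholdSpec(site_dp_min=550.0, mq_lo=59.0, mq_hi=61.0, vqslod_min=3.0)
        outcomes = run_independent(ds, spec, site_indices=biallelic_indices)
        totals = {
            (o.confusion.total_discordant, o.confusion.total_concordant)
            for fid, o in outcomes.items()
            if o.unit == "sites"
        }
        assert len(totals) == 1  # same input -> same pair-observation margins


class TestBlacklistFilter:
    def test_interval_removal_counts(self):
        sites = [snv(100), snv(250), snv(300)]
        ds = make_dataset(sites, [[(0, 1)]] * 3)
        iset = IntervalSet([("1", 99, 100), ("1", 290, 310)])
        passed = variant_pass_mask(ds, "blacklist_lcr", ThresholdSpec(), [iset])
        assert list(passed) == [False, True, False]
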