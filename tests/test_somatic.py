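"""CCF estimation, segment classes, parsing, and the FFPE artifact test."""

import warnings

import numpy as np
import pandas as pd
import pytest

from neoclone.somatic import (
    SegmentCall,
    VariantCall,
    annotate_variants,
    classify_segment,
    estimate_ccf,
    estimate_ccf_table,
    ffpe_transition_test,
    read_segments,
    read_somatic_inputs,
    read_vcf,
)


def make_variant(vaf, depth=200, **kw):
    alt = int(round(vaf * depth))
    return VariantCall("1", 100, "A", "T", depth - alt, alt, **kw)


def hand_ccf(vaf, purity, cnt, major):
    """Independent closed-form oracle for the CCF transformation."""
    denom = purity * cnt + (1 - purity) * 2
    m = min(max(round(vaf * denom / purity), 1), major)
    return vaf * denom / (purity * m), m


class TestEstimateCcf:
    def test_matches_closed_form_on_grid(self):
        for purity in (0.2, 0.4, 0.6, 0.8, 1.0):
            for major, minor in ((1, 1), (2, 1), (2, 0), (3, 1)):
                for vaf in (0.0, 0.05, 0.1, 0.25, 0.4, 0.5):
                    seg = SegmentCall("1", 0, 1000, major, minor, 1.0)
                    v = make_variant(vaf, depth=1000)
                    est = estimate_ccf(v, seg, purity)
                    expected, m = hand_ccf(v.vaf, purity, major + minor, major)
                    assert est.multiplicity == m
                    assert est.ccf == pytest.approx(
                        min(expected, 1.5), abs=1e-9
                    )

    def test_clonal_heterozygous_limit(self):
        seg = SegmentCall("1", 0, 1000, 1, 1, 1.0)
        est = estimate_ccf(make_variant(0.5), seg, purity=1.0)
        assert est.multiplicity == 1
        assert est.ccf == pytest.approx(1.0, abs=1e-12)

    def test_hand_calculation_subclonal(self):
        # purity 0.6, diploid, VAF 0.15 -> ccf = 0.15*2/0.6 = 0.5
        seg = SegmentCall("1", 0, 1000, 1, 1, 1.0)
        est = estimate_ccf(make_variant(0.15, depth=100), seg, purity=0.6)
        assert est.ccf == pytest.approx(0.5, abs=1e-12)

    def test_zero_vaf_gives_zero_ccf(self):
        seg = SegmentCall("1", 0, 1000, 2, 1, 1.0)
        for purity in (0.3, 0.7, 1.0):
            assert estimate_ccf(make_variant(0.0), seg, purity).ccf == 0.0

    def test_zero_tumor_copies_undefined(self):
        seg = SegmentCall("1", 0, 1000, 0, 0, 1.0)
        with pytest.raises(ValueError, match="CNt = 0"):
            estimate_ccf(make_variant(0.1), seg, purity=1.0)

    def test_scale_consistency_doubling_reads(self):
        seg = SegmentCall("1", 0, 1000, 1, 1, 1.0)
        v1 = VariantCall("1", 100, "A", "T", 170, 30)
        v2 = VariantCall("1", 100, "A", "T", 340, 60)
        e1 = estimate_ccf(v1, seg, 0.6)
        e2 = estimate_ccf(v2, seg, 0.6)
        assert e1.ccf == pytest.approx(e2.ccf, abs=1e-12)
        assert (e2.ci_high - e2.ci_low) < (e1.ci_high - e1.ci_low)

    def test_flagged_above_one(self):
        seg = SegmentCall("1", 0, 1000, 1, 1, 1.0)
        est = estimate_ccf(make_variant(0.5), seg, purity=0.6)
        assert est.flagged
        assert est.ccf <= 1.5

    def test_table_agrees_with_scalar(self):
        seg = SegmentCall("1", 0, 1000, 2, 1, 1.0)
        rows = []
        for vaf in (0.1, 0.2, 0.35):
            v = make_variant(vaf, depth=150)
            rows.append({
                "sample_id": "s", "chrom": "1", "pos": 100, "ref": "A",
                "alt": "T", "ref_count": v.ref_count, "alt_count": v.alt_count,
                "major_cn": 2, "minor_cn": 1, "cn_fraction": 1.0,
                "in_segment": True,
            })
        table = estimate_ccf_table(pd.DataFrame(rows), purity=0.7)
        for i, vaf in enumerate((0.1, 0.2, 0.35)):
            scalar = estimate_ccf(make_variant(vaf, depth=150), seg, 0.7)
            assert table["ccf"].iloc[i] == pytest.approx(scalar.ccf, abs=1e-12)
            assert table["multiplicity"].iloc[i] == scalar.multiplicity


class TestClassifySegment:
    def seg(self, frac, major=1, minor=0, sample="s1", start=0, end=1000):
        return SegmentCall("1", start, end, major, minor, frac, sample)

    def test_subclonal_loss(self):
        assert classify_segment(self.seg(0.5), 2.0) == "subclonal"

    def test_clonal_threshold(self):
        assert classify_segment(self.seg(0.95), 2.0) == "clonal"
        assert classify_segment(self.seg(0.9), 2.0) == "clonal"

    def test_rescued_by_other_sample(self):
        others = [self.seg(0.3, sample="s2")]
        assert classify_segment(self.seg(0.05), 2.0, others) == "rescued-subclonal"

    def test_not_rescued_when_other_sample_low(self):
        others = [self.seg(0.05, sample="s2")]
        assert classify_segment(self.seg(0.05), 2.0, others) == "absent"

    def test_not_rescued_by_non_loss(self):
        others = [SegmentCall("1", 0, 1000, 1, 1, 0.5, "s2")]
        assert classify_segment(self.seg(0.05), 2.0, others) == "absent"

    def test_excluded_sample(self):
        assert classify_segment(self.seg(0.5), 2.0, purity_clear=False) == "excluded"

    def test_order_invariance_of_rescue(self):
        others = [self.seg(0.02, sample="s3"), self.seg(0.3, sample="s2")]
        a = classify_segment(self.seg(0.05), 2.0, others)
        b = classify_segment(self.seg(0.05), 2.0, list(reversed(others)))
        assert a == b == "rescued-subclonal"


class TestParsing:
    def test_vcf_round_trip(self, small_cohort, small_cohort_dir):
        sid = small_cohort.samples["sample"].iloc[0]
        got = read_vcf(small_cohort_dir / "vcf" / f"{sid}.vcf")
        want = (small_cohort.variants[small_cohort.variants["sample_id"] == sid]
                .sort_values(["chrom", "pos"]).reset_index(drop=True))
        got = got.sort_values(["chrom", "pos"]).reset_index(drop=True)
        assert len(got) == len(want)
        assert (got["alt_count"].to_numpy()
                == want["alt_count"].to_numpy()).all()
        assert (got["ref_count"].to_numpy()
                == want["ref_count"].to_numpy()).all()

    def test_empty_vcf_body(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        assert read_vcf(path).empty

    def test_missing_ad_field_rejected(self, tmp_path):
        path = tmp_path / "noad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:30\n"
        )
        with pytest.raises(ValueError, match="AD"):
            read_vcf(path)

    def test_invalid_segment_interval(self, tmp_path):
        path = tmp_path / "segs.tsv"
        pd.DataFrame({
            "sample_id": ["s"], "chrom": ["1"], "start": [500], "end": [100],
            "major_cn": [1], "minor_cn": [1], "cn_fraction": [1.0],
        }).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="start >= end"):
            read_segments(path)

    def test_read_somatic_inputs_annotates_segments(self, small_cohort_dir,
                                                    small_cohort):
        sid = small_cohort.samples["sample"].iloc[0]
        variants, segments, samples = read_somatic_inputs(
            {sid: small_cohort_dir / "vcf" / f"{sid}.vcf"},
            small_cohort_dir / "segments.tsv",
            small_cohort_dir / "samples.csv",
        )
        assert variants["in_segment"].all()  # toy genome fully segmented
        assert set(variants["major_cn"].unique()) == {1.0}

    def test_variant_outside_segments_flagged(self):
        variants = pd.DataFrame({
            "sample_id": ["s"], "chrom": ["1"], "pos": [5000], "ref": ["A"],
            "alt": ["T"], "ref_count": [90], "alt_count": [10],
        })
        segments = pd.DataFrame({
            "sample_id": ["s"], "chrom": ["1"], "start": [0], "end": [1000],
            "major_cn": [1], "minor_cn": [1], "cn_fraction": [1.0],
        })
        out = annotate_variants(variants, segments)
        assert not out["in_segment"].iloc[0]


class TestFfpeTransitionTest:
    def _pair_tables(self, fracs_ff, fracs_ffpe, n=50):
        """Build per-patient variant tables with given deamination fractions."""
        ff, ffpe = {}, {}
        for i, (a, b) in enumerate(zip(fracs_ff, fracs_ffpe)):
            for frac, d in ((a, ff), (b, ffpe)):
                k = int(round(frac * n))
                refs = ["C"] * k + ["A"] * (n - k)
                alts = ["T"] * k + ["G"] * (n - k)
                d[f"p{i}"] = pd.DataFrame({
                    "ref": refs, "alt": alts,
                    "ref_count": [95] * n, "alt_count": [5] * n,  # VAF 0.05
                })
        return ff, ffpe

    def test_identical_fractions_p_one(self):
        ff, ffpe = self._pair_tables([0.2] * 4, [0.2] * 4)
        res = ffpe_transition_test(ff, ffpe)
        low = res[res["vaf_bin"] == "[0.01,0.1)"].iloc[0]
        assert low["p_value"] == 1.0

    def test_forced_enrichment_rejects(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.2, 8)
        ff, ffpe = self._pair_tables(base, base + 0.3)
        res = ffpe_transition_test(ff, ffpe)
        low = res[res["vaf_bin"] == "[0.01,0.1)"].iloc[0]
        assert low["p_value"] < 0.05
        assert low["mean_diff"] == pytest.approx(0.3, abs=0.02)

    def test_pair_without_bin_snvs_dropped_with_warning(self):
        ff, ffpe = self._pair_tables([0.2] * 3, [0.2] * 3)
        # patient p0 gets only high-VAF variants: empty low bin
        for d in (ff, ffpe):
            d["p0"] = d["p0"].assign(alt_count=50, ref_count=50)
        with pytest.warns(UserWarning, match="pair dropped"):
            res = ffpe_transition_test(ff, ffpe)
        low = res[res["vaf_bin"] == "[0.01,0.1)"].iloc[0]
        assert low["n_pairs"] == 2

    def test_fewer_than_two_pairs_rejected(self):
        ff, ffpe = self._pair_tables([0.2], [0.2])
        with pytest.raises(ValueError, match=">= 2 matched"):
            ffpe_transition_test(ff, ffpe)
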