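"""Binomial-mixture clone clustering, matching, and segment-pair comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone as sk_clone

from neoclone.clonal import (
    BinomialMixtureCCF,
    cluster_ccfs,
    compare_segment_pairs,
    match_longitudinal,
)


def planted_table(seed, ccfs=(1.0, 0.4), n=100, depth=200, purity=0.6):
    rng = np.random.default_rng(seed)
    ccf = np.repeat(ccfs, n // len(ccfs))
    w = purity / 2.0  # diploid, single mutated copy
    d = np.maximum(rng.poisson(depth, len(ccf)), 1)
    alt = rng.binomial(d, w * ccf)
    return pd.DataFrame({"alt_count": alt, "ref_count": d - alt,
                         "p_per_ccf": w})


def seg_frame(rows, sample="s"):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "major_cn", "minor_cn",
                       "cn_fraction"]
    ).assign(sample_id=sample)


class TestBinomialMixture:
    def test_loglik_nondecreasing_every_iteration(self):
        tbl = planted_table(0)
        X = np.c_[tbl["alt_count"], tbl["alt_count"] + tbl["ref_count"],
                  tbl["p_per_ccf"]]
        for k in (1, 2, 3, 4):
            m = BinomialMixtureCCF(n_components=k).fit(X)
            assert np.all(np.diff(m.loglik_path_) >= -1e-7)

    def test_sklearn_estimator_protocol(self):
        m = BinomialMixtureCCF(n_components=3, random_state=7)
        params = m.get_params()
        assert params["n_components"] == 3
        m2 = sk_clone(m).set_params(n_components=2)
        assert m2.get_params()["n_components"] == 2
        tbl = planted_table(1)
        X = np.c_[tbl["alt_count"], tbl["alt_count"] + tbl["ref_count"],
                  tbl["p_per_ccf"]]
        m2.fit(X)
        assert len(m2.ccfs_) == 2
        assert m2.predict(X).shape == (len(X),)

    def test_same_seed_same_fit(self):
        tbl = planted_table(2)
        X = np.c_[tbl["alt_count"], tbl["alt_count"] + tbl["ref_count"],
                  tbl["p_per_ccf"]]
        a = BinomialMixtureCCF(n_components=3, random_state=5).fit(X)
        b = BinomialMixtureCCF(n_components=3, random_state=5).fit(X)
        assert np.array_equal(a.ccfs_, b.ccfs_)
        assert np.array_equal(a.labels_, b.labels_)


class TestClusterCcfs:
    def test_single_clone_collapses_to_one_cluster(self):
        tbl = pd.DataFrame({
            "alt_count": [30] * 20, "ref_count": [70] * 20,
            "p_per_ccf": [0.3] * 20,
        })
        clusters, labels = cluster_ccfs(tbl, k_max=6, seed=0)
        assert len(clusters) == 1
        assert clusters["n_variants"].iloc[0] == 20

    def test_two_planted_clones_recovered(self):
        hits = 0
        for seed in range(10):
            clusters, _ = cluster_ccfs(planted_table(seed), k_max=6, seed=0)
            if len(clusters) == 2:
                m = np.sort(clusters["mean_ccf"].to_numpy())
                if abs(m[0] - 0.4) < 0.05 and abs(m[1] - 1.0) < 0.05:
                    hits += 1
        assert hits >= 9

    def test_too_few_estimates_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            cluster_ccfs(planted_table(0).head(4))

    def test_cluster_sizes_partition_variants(self):
        tbl = planted_table(3)
        clusters, labels = cluster_ccfs(tbl, seed=0)
        assert clusters["n_variants"].sum() == len(tbl)
        assert (clusters["mean_ccf"] <= 1.5).all()


class TestMatchLongitudinal:
    def test_stable_pair(self):
        changes = match_longitudinal([1.0, 0.4], [1.0, 0.4])
        assert list(changes["direction"]) == ["stable", "stable"]

    def test_extinct_cluster(self):
        changes = match_longitudinal([1.0, 0.4], [1.0])
        assert sorted(changes["direction"]) == ["extinct", "stable"]

    def test_emerging_cluster(self):
        changes = match_longitudinal([1.0], [1.0, 0.3])
        assert sorted(changes["direction"]) == ["emerging", "stable"]

    def test_growth_and_shrinkage_by_sign(self):
        changes = match_longitudinal([0.6], [0.9], delta=0.1)
        assert list(changes["direction"]) == ["growing"]
        changes = match_longitudinal([0.6], [0.3], delta=0.1)
        assert list(changes["direction"]) == ["shrinking"]

    def test_empty_sides(self):
        changes = match_longitudinal([], [0.5])
        assert list(changes["direction"]) == ["emerging"]
        changes = match_longitudinal([0.5], [])
        assert list(changes["direction"]) == ["extinct"]

    def test_relabeling_invariance(self):
        pre = pd.DataFrame({"mean_ccf": [1.0, 0.4, 0.2],
                            "n_variants": [50, 30, 10]})
        post = pd.DataFrame({"mean_ccf": [0.45, 1.0], "n_variants": [25, 60]})
        a = match_longitudinal(pre, post)
        b = match_longitudinal(pre.iloc[::-1].reset_index(drop=True),
                               post.iloc[::-1].reset_index(drop=True))
        key = ["pre_ccf", "post_ccf", "delta_ccf", "direction"]
        sa = a[key].sort_values(key[:2]).reset_index(drop=True)
        sb = b[key].sort_values(key[:2]).reset_index(drop=True)
        pd.testing.assert_frame_equal(sa, sb)


class TestCompareSegmentPairs:
    def test_identical_segments_on_diagonal(self):
        segs = seg_frame([
            ("1", 0, 1_000_000, 1, 0, 0.5),
            ("1", 1_000_000, 2_000_000, 1, 1, 1.0),
            ("2", 0, 500_000, 0, 0, 0.3),
        ])
        pairs, shift, _ = compare_segment_pairs(segs, segs)
        assert len(pairs) == 3
        assert (pairs["cn_fraction_pre"] == pairs["cn_fraction_post"]).all()
        assert shift == 0.0

    def test_depleted_subclone_shifts(self):
        pre = seg_frame([
            ("1", 0, 1_000_000, 1, 0, 0.4),
            ("2", 0, 1_000_000, 1, 0, 0.45),
            ("3", 0, 1_000_000, 1, 1, 1.0),
        ])
        post = seg_frame([
            ("1", 0, 1_000_000, 1, 0, 0.05),
            ("2", 0, 1_000_000, 1, 0, 0.04),
            ("3", 0, 1_000_000, 1, 1, 1.0),
        ])
        pairs, shift, _ = compare_segment_pairs(pre, post)
        assert shift == pytest.approx(1.0)

    def test_disjoint_coordinates_missing_statistic(self):
        pre = seg_frame([("1", 0, 1000, 1, 0, 0.4)])
        post = seg_frame([("2", 0, 1000, 1, 0, 0.4)])
        pairs, shift, kde = compare_segment_pairs(pre, post)
        assert pairs.empty
        assert np.isnan(shift)
        assert kde is None

    def test_reciprocal_overlap_required(self):
        pre = seg_frame([("1", 0, 1_000_000, 1, 0, 0.4)])
        # only 10% of the pre segment covered: no match at 50% reciprocal
        post = seg_frame([("1", 900_000, 1_000_000, 1, 0, 0.4)])
        pairs, shift, _ = compare_segment_pairs(pre, post)
        assert pairs.empty

    def test_empty_input_rejected(self):
        segs = seg_frame([("1", 0, 1000, 1, 0, 0.4)])
        with pytest.raises(ValueError, match="both timepoints"):
            compare_segment_pairs(segs, segs.iloc[:0])
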