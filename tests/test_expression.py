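"""Normalization, differential expression, BH-FDR, PCA, junction ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoclone.expression import (
    bh_adjust,
    de_test,
    filter_candidates,
    junction_ratio,
    log_cpm,
    pca_variance,
    size_factors,
)


def bh_oracle(p):
    """Brute-force BH: sort, n*p/rank, cumulative minimum from the right."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


class TestLogCpm:
    def test_single_gene_closed_form(self):
        c = 500
        m = pd.DataFrame({"s1": [c]}, index=["g1"])
        got = log_cpm(m).iloc[0, 0]
        assert got == pytest.approx(np.log2(1e6 * (c + 0.5) / (c + 1)),
                                    abs=1e-12)

    def test_all_zero_gene_identical_across_equal_libraries(self):
        m = pd.DataFrame({"s1": [100, 0], "s2": [100, 0]},
                         index=["g1", "g2"])
        lcpm = log_cpm(m)
        assert lcpm.loc["g2", "s1"] == pytest.approx(lcpm.loc["g2", "s2"])
        assert lcpm.loc["g2"].min() == lcpm.min().min()

    def test_scaling_one_sample_is_absorbed_by_size_factor(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(100, (50, 4)),
                         index=[f"g{i}" for i in range(50)],
                         columns=list("abcd"))
        m2 = m.copy()
        m2["a"] = m2["a"] * 2
        got = log_cpm(m2)["a"]
        want = log_cpm(m)["a"]
        # doubling one sample doubles its *relative* size factor exactly;
        # log-CPM matches up to the prior-count term
        sf1, sf2 = size_factors(m), size_factors(m2)
        assert (sf2["a"] / sf2["b"]) == pytest.approx(
            2 * sf1["a"] / sf1["b"], abs=1e-9
        )
        assert np.allclose(got, want, atol=0.01)

    def test_zero_library_rejected(self):
        m = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero library"):
            log_cpm(m)

    def test_duplicate_gene_ids_rejected(self):
        m = pd.DataFrame({"s1": [1, 2]}, index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate"):
            log_cpm(m)


class TestBhAdjust:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDeTest:
    def _matrix(self, seed=0, n_genes=60, n1=3, n2=3):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.poisson(200, (n_genes, n1 + n2)),
                         index=[f"g{i:03d}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(n1 + n2)])
        groups = pd.Series(["T"] * n1 + ["C"] * n2, index=m.columns)
        return m, groups

    def test_identical_groups_zero_logfc(self):
        m, _ = self._matrix()
        dup = pd.concat([m, m.add_suffix("_r")], axis=1)
        groups = pd.Series(["T"] * m.shape[1] + ["C"] * m.shape[1],
                           index=dup.columns)
        de = de_test(dup, groups, treated="T", control="C")
        assert np.allclose(de["logFC"], 0.0)
        assert (de.loc[de["tested"], "p"] == 1.0).all()

    def test_gene_and_sample_order_invariance(self):
        m, groups = self._matrix(seed=3)
        de1 = de_test(m, groups, treated="T", control="C")
        shuffled = m.sample(frac=1, random_state=0)  # gene order
        cols = ["s1", "s0", "s2", "s5", "s3", "s4"]  # within-group order
        de2 = de_test(shuffled[cols], groups[cols], treated="T", control="C")
        pd.testing.assert_frame_equal(de1.sort_index(), de2.sort_index())

    def test_one_small_group_rejected(self):
        m, _ = self._matrix()
        groups = pd.Series(["T"] + ["C"] * 5, index=m.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            de_test(m, groups, treated="T", control="C")

    def test_fdr_at_least_p(self):
        m, groups = self._matrix(seed=5)
        de = de_test(m, groups, treated="T", control="C")
        t = de[de["tested"]]
        assert (t["fdr"] >= t["p"] - 1e-12).all()


class TestFilterCandidates:
    def _de(self):
        return pd.DataFrame({
            "logFC": [2.0, 1.0, 2.0, 2.0],
            "fdr": [0.01, 0.01, 0.2, 0.01],
            "logCPM": [5.0, 5.0, 5.0, 2.0],
            "tested": True,
        }, index=["keep", "boundary_lfc", "high_fdr", "low_abund"])

    def test_threshold_triple(self):
        assert filter_candidates(self._de()) == ["keep"]

    def test_strict_boundary_excluded(self):
        assert "boundary_lfc" not in filter_candidates(self._de())

    def test_noop_bounds_return_all(self):
        de = self._de()
        got = filter_candidates(de, 0.0, 1.1, -np.inf)
        assert got == list(de.index)


class TestPcaVariance:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(300, (100, 10)),
                         index=[f"g{i}" for i in range(100)],
                         columns=[f"s{i}" for i in range(10)])
        frac = pca_variance(m)
        x = log_cpm(m).to_numpy().T
        x = x - x.mean(axis=0)
        ev = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        want = ev[: len(frac)] / ev.sum()
        assert np.allclose(frac, want, atol=1e-8)
        assert frac.sum() == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_structure_dominates(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 1, 200)
        # half the genes x8 in half the samples: one strong latent axis
        # (a uniform scaling would be absorbed as library size)
        effect = np.ones(200)
        effect[:100] = 8.0
        cols = {f"s{i}": rng.poisson(base * (effect if i >= 5 else 1.0))
                for i in range(10)}
        m = pd.DataFrame(cols, index=[f"g{i}" for i in range(200)])
        frac = pca_variance(m)
        assert frac[0] > 0.9

    def test_constant_matrix_zero_fractions(self):
        m = pd.DataFrame({"s1": [5, 7], "s2": [5, 7]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="zero variance"):
            frac = pca_variance(m)
        assert np.allclose(frac, 0.0)

    def test_single_sample_rejected(self):
        m = pd.DataFrame({"s1": [5, 7]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            pca_variance(m)


class TestJunctionRatio:
    def test_zero_variant_reads(self):
        r = junction_ratio(0, 200)
        assert r.ratio == 0.0
        assert r.defined

    def test_below_one_percent_regime(self):
        r = junction_ratio(1, 200)
        assert r.ratio == pytest.approx(0.005)
        assert r.ratio < 0.01
        assert r.ci_low <= 1 / 201 <= r.ci_high

    def test_no_canonical_reads_undefined(self):
        r = junction_ratio(5, 0)
        assert not r.defined
        assert np.isnan(r.ratio)

    def test_both_zero_undefined(self):
        assert not junction_ratio(0, 0).defined

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            junction_ratio(-1, 5)
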