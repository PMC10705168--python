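import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maculaseq.containers import CountMatrix
from maculaseq.expression import (
    bh_adjust,
    fpkm,
    nb_dispersion_mom,
    nb_wald_test,
    significant_degs,
    size_factors_median_of_ratios,
    size_factors_tmm,
)
from maculaseq.thresholds import Thresholds


def bh_oracle(p):
    """Brute-force step-up: q_i = min over k >= rank_i of p_(k) * m / k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.minimum(q, 1.0)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        sf = size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        counts = pd.DataFrame({"s1": [10, 40, 7], "s2": [20, 80, 14]})
        sf = size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = size_factors_median_of_ratios(counts)
        values = counts.to_numpy(dtype=float)
        geo = np.exp(np.log(values).mean(axis=1))
        expected = [np.median(values[:, j] / geo) for j in range(6)]
        np.testing.assert_allclose(sf, expected, rtol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(1, 200, size=(30, 4)),
                              columns=list("abcd"))
        sf = size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["a"] = counts["a"] * 3
        sf2 = size_factors_median_of_ratios(scaled)
        # multiplying one sample by c multiplies its factor by c (relative to
        # the new geometric mean 3^{1/4})
        np.testing.assert_allclose(sf2["a"] / sf["a"], 3 / 3 ** (1 / 4), rtol=1e-12)

    def test_all_zero_gene_row_everywhere_raises(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_of_ratios(counts)

    def test_tmm_identical_samples_unit(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [10, 20, 30, 40]})
        np.testing.assert_allclose(size_factors_tmm(counts), [1.0, 1.0], atol=1e-12)

    def test_tmm_pure_scaling_recovered(self):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 1000, size=200)
        counts = pd.DataFrame({"s1": base, "s2": base * 4})
        sf = size_factors_tmm(counts)
        np.testing.assert_allclose(sf["s2"] / sf["s1"], 4.0, rtol=1e-6)

    def test_tmm_robust_to_asymmetric_composition_change(self):
        """30% of genes 8-fold up in one sample: the trimmed factor should sit
        closer to 1 than the naive total-count ratio."""
        rng = np.random.default_rng(9)
        base = rng.integers(50, 500, size=300)
        up = base.copy()
        up[:90] = up[:90] * 8
        counts = pd.DataFrame({"ref": base, "shifted": up})
        sf = size_factors_tmm(counts, reference="ref")
        naive = up.sum() / base.sum()
        tmm_ratio = sf["shifted"] / sf["ref"]
        assert abs(np.log(tmm_ratio)) < abs(np.log(naive))


class TestFpkm:
    def test_textbook_value(self):
        counts = pd.DataFrame({"s": [500]}, index=["g"])
        out = fpkm(counts, pd.Series({"g": 2000}), pd.Series({"s": 10_000_000}))
        assert out.loc["g", "s"] == pytest.approx(25.0)

    def test_zero_count_zero_and_formula_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(20, 3)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("xyz"))
        lengths = pd.Series(rng.integers(200, 9000, size=20), index=counts.index)
        totals = pd.Series(rng.integers(10**6, 10**7, size=3), index=counts.columns)
        out = fpkm(counts, lengths, totals)
        for g in counts.index[:5]:
            for s in counts.columns:
                expected = counts.loc[g, s] / (lengths[g] / 1e3) / (totals[s] / 1e6)
                assert out.loc[g, s] == pytest.approx(expected, rel=1e-12)
        assert (out.to_numpy()[counts.to_numpy() == 0] == 0).all()

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s": [5]}, index=["g"])
        with pytest.raises(ValueError, match="missing"):
            fpkm(counts, pd.Series(dtype=float), pd.Series({"s": 1e6}))


class TestDispersion:
    def test_constant_counts_zero(self):
        assert nb_dispersion_mom([10, 10, 10, 10]) == 0.0

    def test_poisson_boundary_zero(self):
        # variance equal to the mean sits exactly at the Poisson limit
        y = [8, 12, 10, 10]  # mean 10, var 8/3 < 10 -> truncated to 0
        assert nb_dispersion_mom(y) == 0.0

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(8)
        mu, alpha = 200.0, 0.2
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=200))
        assert 0.1 <= nb_dispersion_mom(y) <= 0.3

    def test_all_zero_is_nan(self):
        assert np.isnan(nb_dispersion_mom([0, 0, 0]))


class TestBHAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], rtol=1e-12
        )

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=25)
    )
    def test_matches_oracle_and_is_monotone(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-10, atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))


class TestNBWald:
    def build(self, counts_by_sample, groups):
        counts = pd.DataFrame(counts_by_sample)
        counts.index = [f"g{i}" for i in range(len(counts))]
        samples = pd.DataFrame(
            {"group": [groups[s] for s in counts.columns], "tissue": "RPE_choroid"},
            index=pd.Index(list(counts.columns), name="sample"),
        )
        return CountMatrix(counts, samples)

    def test_identical_groups_null_identity(self):
        col = [50, 120, 7, 300]
        cm = self.build(
            {"a1": col, "a2": col, "b1": col, "b2": col},
            {"a1": "normal", "a2": "normal", "b1": "iAMD", "b2": "iAMD"},
        )
        res = nb_wald_test(cm, ("iAMD", "normal"))
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(1)
        data = {f"a{i}": rng.poisson(100, size=30) for i in range(4)}
        data.update({f"b{i}": rng.poisson(130, size=30) for i in range(4)})
        groups = {s: ("normal" if s.startswith("a") else "iAMD") for s in data}
        cm = self.build(data, groups)
        fwd = nb_wald_test(cm, ("iAMD", "normal")).table
        rev = nb_wald_test(cm, ("normal", "iAMD")).table
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-10)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-10)

    def test_relabeling_within_group_invariant(self):
        rng = np.random.default_rng(2)
        data = {f"a{i}": rng.poisson(80, size=20) for i in range(3)}
        data.update({f"b{i}": rng.poisson(80, size=20) for i in range(3)})
        groups = {s: ("normal" if s.startswith("a") else "iAMD") for s in data}
        cm = self.build(data, groups)
        base = nb_wald_test(cm, ("iAMD", "normal")).table
        shuffled = cm.subset_samples(["a2", "a0", "a1", "b1", "b2", "b0"])
        perm = nb_wald_test(shuffled, ("iAMD", "normal")).table
        np.testing.assert_allclose(base["p"], perm["p"], rtol=1e-12)

    def test_all_zero_gene_excluded_and_recorded(self):
        cm = self.build(
            {"a1": [10, 0], "a2": [12, 0], "b1": [9, 0], "b2": [11, 0]},
            {"a1": "normal", "a2": "normal", "b1": "iAMD", "b2": "iAMD"},
        )
        res = nb_wald_test(cm, ("iAMD", "normal"))
        assert list(res.excluded["gene"]) == ["g1"]
        assert "g1" not in set(res.table["gene"])

    def test_too_few_samples_rejected(self):
        cm = self.build(
            {"a1": [10], "b1": [9], "b2": [11]},
            {"a1": "normal", "b1": "iAMD", "b2": "iAMD"},
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_test(cm, ("iAMD", "normal"))


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "padj,fold,kept",
        [(0.04, 1.6, True), (0.04, 1.4, False), (0.06, 3.0, False), (0.04, 1.0 / 1.6, True)],
    )
    def test_padj_and_fold_thresholds(self, padj, fold, kept):
        table = pd.DataFrame(
            {"gene": ["g"], "log2fc": [np.log2(fold)], "padj": [padj]}
        )
        out = significant_degs(table, Thresholds())
        assert (len(out) == 1) is kept
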