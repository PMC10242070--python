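"""Size factors, dispersion, NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahrseq.diffexpr import (
    ALPHA_MIN,
    bh_adjust,
    call_degs,
    de_table,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
)

from .oracles import brute_bh


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        counts = _frame(np.tile([[10], [20], [7]], (1, 4)))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column(self):
        col = np.array([5, 11, 23, 40, 100])
        counts = _frame(np.column_stack([col, 2 * col]))
        sf = estimate_size_factors(counts)
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = _frame(rng.poisson(50, size=(30, 6)) + 1)
        sf = estimate_size_factors(counts)
        perm = list(counts.columns[::-1])
        sf_perm = estimate_size_factors(counts[perm])
        assert np.allclose(sf_perm.to_numpy(), sf[perm].to_numpy())

    def test_pseudocount_fallback(self, caplog):
        counts = _frame([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            estimate_size_factors(counts, pseudocount_fallback=False)
        sf = estimate_size_factors(counts)  # falls back, logged
        assert (sf > 0).all()

    def test_column_scaling_absorbed_into_global_factor(self):
        """Scaling one sample's counts is absorbed by the size factors: every
        normalized value changes by one common constant, so all between-group
        fold changes are invariant."""
        rng = np.random.default_rng(1)
        counts = _frame(rng.poisson(80, size=(50, 4)) + 1)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 3
        norm = counts / estimate_size_factors(counts)
        norm_scaled = scaled / estimate_size_factors(scaled)
        ratio = (norm_scaled / norm).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])


class TestDispersion:
    def test_worked_example_mean10_var30(self):
        # one gene, one group: normalized mean 10, sample variance 30
        counts = _frame([[4, 7, 13, 16]])
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, [list(counts.columns)])
        assert disp.iloc[0] == pytest.approx((30 - 10) / 10**2)

    def test_floor_when_variance_below_mean(self):
        counts = _frame([[10, 10, 10, 10]])
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, [list(counts.columns)])
        assert disp.iloc[0] == ALPHA_MIN

    def test_all_singleton_groups_rejected(self):
        counts = _frame([[1, 2], [3, 4]])
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError):
            estimate_dispersion(counts, sf, [["s0"], ["s1"]])

    def test_recovery_median_in_window(self):
        """Simulated at alpha = 0.1 with n = 24/group, the median gene-wise
        estimate lands in [0.07, 0.13]; moderation preserves the median."""
        rng = np.random.default_rng(42)
        n, G, alpha = 24, 2000, 0.1
        mu = np.exp(rng.uniform(np.log(20), np.log(500), G))[:, None]
        r = 1 / alpha
        counts = _frame(rng.negative_binomial(r, r / (r + mu), size=(G, 2 * n)))
        sf = estimate_size_factors(counts)
        groups = [list(counts.columns[:n]), list(counts.columns[n:])]
        for moderate in (False, True):
            disp = estimate_dispersion(counts, sf, groups, moderate=moderate)
            assert 0.07 <= np.median(disp) <= 0.13


class TestWald:
    def test_identical_groups_null(self):
        counts = _frame(np.tile([[30], [7]], (1, 8)))
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = nb_wald_test(counts, sf, disp, (list(counts.columns[:4]),
                                              list(counts.columns[4:])))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_all_zero_gene_degenerate(self):
        counts = _frame([[0] * 8, [50] * 8])
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = nb_wald_test(counts, sf, disp, (list(counts.columns[:4]),
                                              list(counts.columns[4:])))
        assert res.loc[0, "log2fc"] == 0.0 and res.loc[0, "p"] == 1.0

    def test_planted_fourfold_consistency(self):
        rng = np.random.default_rng(7)
        n, alpha = 24, 0.1
        r = 1 / alpha
        mu = np.concatenate([np.full(n, 100.0), np.full(n, 400.0)])
        counts = _frame(rng.negative_binomial(r, r / (r + mu), size=(1, 2 * n)))
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(alpha, index=counts.index)
        res = nb_wald_test(counts, sf, disp, (list(counts.columns[:n]),
                                              list(counts.columns[n:])))
        assert abs(res.loc[0, "log2fc"] - 2.0) < 0.2

    def test_contrast_swap_negates_lfc(self):
        rng = np.random.default_rng(3)
        counts = _frame(rng.poisson(100, size=(40, 8)) + 1)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        a, b = list(counts.columns[:4]), list(counts.columns[4:])
        fwd = nb_wald_test(counts, sf, disp, (a, b))
        rev = nb_wald_test(counts, sf, disp, (b, a))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_empty_group_rejected(self):
        counts = _frame([[1, 2]])
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        with pytest.raises(ValueError):
            nb_wald_test(counts, sf, disp, ([], ["s0"]))


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_bh(p), atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_brute_force_property(self, ps):
        p = np.array(ps)
        assert np.allclose(bh_adjust(p), brute_bh(p), atol=1e-12)


class TestCallDegs:
    def test_strict_threshold(self):
        records = pd.DataFrame({"gene_id": ["a", "b"], "fdr": [0.0099, 0.01]})
        out = call_degs(records)
        assert out["is_deg"].tolist() == [True, False]

    def test_empty(self):
        out = call_degs(pd.DataFrame({"gene_id": [], "fdr": []}))
        assert len(out) == 0


def test_de_table_end_to_end_types():
    rng = np.random.default_rng(5)
    counts = _frame(rng.poisson(60, size=(100, 8)) + 1)
    sf = estimate_size_factors(counts)
    disp = estimate_dispersion(counts, sf, [list(counts.columns[:4]),
                                            list(counts.columns[4:])])
    tab = de_table(counts, sf, disp, (list(counts.columns[:4]),
                                      list(counts.columns[4:])))
    assert set(tab.columns) == {"gene_id", "log2fc", "se", "p", "fdr", "is_deg"}
    assert ((tab["fdr"] >= tab["p"] - 1e-12) | tab["p"].isna()).all()
    assert tab["fdr"].between(0, 1).all()
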