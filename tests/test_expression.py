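import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orphanlc.expression import (
    _exact_spearman_p,
    bias_retention_correlation,
    expression_trend_by_age,
    fpkm,
    normalize_counts,
    sex_bias,
    size_factors,
)
from orphanlc.experiments import planted_shift_recovery


def matrix(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))])


def meta(samples, sexes):
    return pd.DataFrame(
        {"sample": samples, "sex": sexes, "strain": ["s"] * len(samples)}
    )


class TestSizeFactors:
    def test_identical_samples(self):
        counts = matrix({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_exact_doubling(self):
        counts = matrix({"a": [10, 20, 5], "b": [20, 40, 10]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_global_scale_invariance(self):
        """Median-of-ratios references the per-gene geometric mean of the
        same matrix, so a global rescaling cancels and factors (hence the
        relative normalisation) are unchanged."""
        counts = matrix({"a": [10, 20, 5], "b": [13, 44, 9]})
        assert np.allclose(size_factors(counts * 10), size_factors(counts))

    def test_single_sample_perturbation(self):
        """Multiplying one sample by c multiplies its factor by c and leaves
        its normalised counts unchanged (up to the shared geometric-mean
        shift)."""
        counts = matrix({"a": [10, 20, 5], "b": [13, 44, 9], "c": [7, 30, 11]})
        f0 = size_factors(counts)
        perturbed = counts.copy()
        perturbed["b"] = perturbed["b"] * 4
        f1 = size_factors(perturbed)
        ratio = f1 / f0
        assert ratio["b"] / ratio["a"] == pytest.approx(4.0)
        n0 = normalize_counts(counts, f0)
        n1 = normalize_counts(perturbed, f1)
        assert np.allclose(n0["b"] / n0["a"], n1["b"] / n1["a"])

    def test_requires_common_nonzero_gene(self):
        counts = matrix({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestFpkm:
    def test_formula(self):
        counts = matrix({"a": [100]})
        out = fpkm(counts, pd.Series({"g0": 1000}), pd.Series({"a": 1_000_000}))
        assert out.loc["g0", "a"] == pytest.approx(100.0)

    def test_zero_count_and_length_scaling(self):
        counts = matrix({"a": [0, 50], "b": [10, 50]})
        lengths = pd.Series({"g0": 500, "g1": 1000})
        libs = pd.Series({"a": 1e6, "b": 1e6})
        out = fpkm(counts, lengths, libs)
        assert out.loc["g0", "a"] == 0.0
        double = fpkm(counts, lengths * 2, libs)
        assert np.allclose(double, out / 2)

    def test_zero_library_size(self):
        with pytest.raises(ValueError):
            fpkm(matrix({"a": [1]}), pd.Series({"g0": 100}), pd.Series({"a": 0}))


class TestSexBias:
    def test_equal_means_unbiased(self):
        counts = matrix({"m1": [50, 10], "m2": [50, 10], "f1": [50, 10], "f2": [50, 10]})
        calls = sex_bias(
            counts, meta(["m1", "m2", "f1", "f2"], ["male", "male", "female", "female"])
        )
        assert np.allclose(calls["log2fc"], 0)
        assert (calls["bias"] == "unbiased").all()

    def test_fourfold_male(self):
        counts = matrix({"m1": [400, 100], "f1": [100, 100], "f2": [100, 100], "m2": [400, 100]})
        calls = sex_bias(
            counts, meta(["m1", "f1", "f2", "m2"], ["male", "female", "female", "male"]),
            factors=pd.Series(1.0, index=counts.columns),
        )
        g0 = calls.set_index("gene_id").loc["g0"]
        assert g0["log2fc"] == pytest.approx(2.0, abs=0.02)
        assert g0["bias"] == "male"

    def test_antisymmetry_under_label_swap(self, rng):
        counts = matrix(
            {c: rng.integers(1, 500, size=30) for c in ["a", "b", "c", "d"]}
        )
        m = meta(["a", "b", "c", "d"], ["male", "male", "female", "female"])
        swapped = meta(["a", "b", "c", "d"], ["female", "female", "male", "male"])
        fc1 = sex_bias(counts, m)["log2fc"]
        fc2 = sex_bias(counts, swapped)["log2fc"]
        assert np.allclose(fc1, -fc2)

    def test_missing_sex_errors(self):
        counts = matrix({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            sex_bias(counts, meta(["a", "b"], ["male", "male"]))

    def test_fdr_test_mode_runs(self, rng):
        counts = matrix(
            {c: rng.integers(50, 500, size=40) for c in ["a", "b", "c", "d"]}
        )
        m = meta(["a", "b", "c", "d"], ["male", "male", "female", "female"])
        calls = sex_bias(counts, m, method="test", fdr=0.1)
        assert set(calls["bias"]) <= {"male", "female", "unbiased"}

    def test_planted_shifts_recovered(self):
        """Recovered group-mean log2fc within 0.2 of each planted shift."""
        recovered = planted_shift_recovery(123)
        for shift, est in recovered.items():
            assert est == pytest.approx(shift, abs=0.2)


class TestBiasRetention:
    def make_calls(self, n, rng):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": np.abs(rng.normal(1.5, 0.8, size=n)) + 0.1,
                "bias": "male",
            }
        )

    def test_monotone_constructed_table(self, rng):
        calls = self.make_calls(700, rng)
        conserved = pd.Series(
            stats.rankdata(calls["log2fc"]) / len(calls) > 0.4,
            index=calls["gene_id"],
        )
        res = bias_retention_correlation(calls, conserved, n_bins=7)
        assert res.rho > 0.8  # top bins saturate at 1.0, tying their ranks
        assert res.p_value < 0.05
        assert len(res.bin_table) == 7

    def test_exact_p_matches_naive_enumeration(self):
        x = np.arange(5.0)
        y = np.array([0.2, 0.1, 0.5, 0.4, 0.6])
        p = _exact_spearman_p(x, y)
        # naive: permute y over all 120 orders
        from itertools import permutations

        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, perm).statistic) >= obs - 1e-12
            for perm in permutations(y)
        )
        assert p == pytest.approx(count / 120)

    def test_too_few_bins(self, rng):
        calls = self.make_calls(10, rng)
        conserved = pd.Series(True, index=calls["gene_id"])
        with pytest.raises(ValueError):
            bias_retention_correlation(calls, conserved, n_bins=20)


class TestExpressionTrend:
    def test_constructed_means(self):
        expr = pd.Series({"g1": 10.0, "g2": 30.0, "g3": 20.0, "g4": 40.0})
        ages = pd.Series({"g1": 3, "g2": 3, "g3": 4, "g4": 4})
        cons = pd.Series({"g1": True, "g2": False, "g3": True, "g4": False})
        table = expression_trend_by_age(expr, ages, cons)
        lookup = table.set_index(["age_class", "group"])["mean_expression"]
        assert lookup[(3, "conserved")] == 10.0
        assert lookup[(4, "lost")] == 40.0

    def test_empty_cell_missing(self):
        expr = pd.Series({"g1": 10.0})
        ages = pd.Series({"g1": 3})
        cons = pd.Series({"g1": True})
        table = expression_trend_by_age(expr, ages, cons)
        lost = table[(table["age_class"] == 3) & (table["group"] == "lost")]
        assert np.isnan(lost["mean_expression"].iloc[0])
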