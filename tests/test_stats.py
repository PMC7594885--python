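"""ICC(A,k), Bland–Altman, summaries and the observer simulator."""
import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from isodrr import (ObserverMatrix, anova_mean_squares, bland_altman,
                    format_summary, icc_a_1, icc_a_k, load_mean_pairs,
                    load_observer_table, simulate_observers,
                    summarize_measurements)


def _matrix(values, **kw):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return ObserverMatrix(values, kw.get("measurements", [f"m{i}" for i in range(n)]),
                          kw.get("modalities", ["x"] * n),
                          [f"obs{j}" for j in range(k)])


def _pingouin_icc(values, icc_type):
    n, k = values.shape
    df = pd.DataFrame([(i, j, values[i, j]) for i in range(n) for j in range(k)],
                      columns=["item", "rater", "score"])
    res = pg.intraclass_corr(df, targets="item", raters="rater", ratings="score")
    return float(res.loc[res["Type"] == icc_type, "ICC"].iloc[0])


class TestICC:
    def test_study_matrix_reaches_excellent_agreement(self):
        icc, lo, hi = icc_a_k(load_observer_table())
        assert round(icc, 3) == 0.999
        assert lo <= icc <= hi
        assert lo > 0.99  # comfortably above the 0.9 "excellent" bar

    def test_identical_raters_give_perfect_agreement(self):
        m = _matrix(np.tile([[10.0], [20.0], [35.0]], (1, 4)))
        icc, lo, hi = icc_a_k(m)
        assert icc == pytest.approx(1.0)

    def test_small_matrix_matches_definitional_anova(self):
        values = np.array([[1, 2, 3], [4, 4, 5], [2, 3, 2], [5, 6, 7]], float)
        n, k = values.shape
        # brute-force sums of squares from first principles
        grand = values.mean()
        ss_rows = k * ((values.mean(1) - grand) ** 2).sum()
        ss_cols = n * ((values.mean(0) - grand) ** 2).sum()
        ss_tot = ((values - grand) ** 2).sum()
        ss_err = ss_tot - ss_rows - ss_cols
        msr, msc, mse = ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (msc - mse) / n)
        got, *_ = icc_a_k(_matrix(values))
        assert got == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(anova_mean_squares(values), (msr, msc, mse))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_independent_implementation_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(50, 10, size=(6, 4)) + rng.normal(0, 3, size=(6, 1))
        assert icc_a_k(_matrix(values))[0] == pytest.approx(
            _pingouin_icc(values, "ICC(A,k)"), abs=1e-10)
        assert icc_a_1(_matrix(values))[0] == pytest.approx(
            _pingouin_icc(values, "ICC(A,1)"), abs=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000),
           shift=st.floats(-100, 100), scale=st.floats(0.1, 50))
    def test_invariant_under_affine_rescaling(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        values = rng.normal(50, 10, size=(5, 4))
        base = icc_a_k(_matrix(values))[0]
        transformed = icc_a_k(_matrix(values * scale + shift))[0]
        assert transformed == pytest.approx(base, abs=1e-9)

    def test_zero_variance_defined_as_perfect(self, caplog):
        m = _matrix(np.full((3, 3), 7.0))
        with caplog.at_level("INFO", logger="isodrr.stats"):
            icc, lo, hi = icc_a_k(m)
        assert (icc, lo, hi) == (1.0, 1.0, 1.0)

    def test_too_few_items_or_raters_rejected(self):
        with pytest.raises(ValueError, match="2 items"):
            _matrix(np.ones((1, 4)))


class TestBlandAltman:
    def test_study_mean_pairs_reproduce_reported_agreement(self):
        _, pairs = load_mean_pairs()
        r = bland_altman(pairs)
        assert round(r.bias_mm, 2) == 0.55
        assert r.sd_mm == pytest.approx(1.255, abs=0.005)
        assert round(r.loa_high_mm, 2) == 3.01
        assert round(r.loa_low_mm, 2) == -1.91

    def test_identical_pairs_collapse_to_zero(self):
        r = bland_altman([(5.0, 5.0), (9.0, 9.0), (2.0, 2.0)])
        assert (r.bias_mm, r.sd_mm, r.loa_low_mm, r.loa_high_mm) == (0, 0, 0, 0)

    def test_symmetric_differences_closed_form(self):
        r = bland_altman([(1.0, 0.0), (0.0, 1.0)])
        assert r.bias_mm == 0.0
        assert r.sd_mm == pytest.approx(np.sqrt(2))
        assert r.loa_high_mm == pytest.approx(1.96 * np.sqrt(2))

    def test_antisymmetric_in_argument_order(self):
        pairs = [(48.3, 47.3), (114.8, 116.3), (26.8, 27.3)]
        fwd = bland_altman(pairs)
        rev = bland_altman([(b, a) for a, b in pairs])
        assert rev.bias_mm == pytest.approx(-fwd.bias_mm)
        assert rev.sd_mm == pytest.approx(fwd.sd_mm)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="two"):
            bland_altman([(1.0, 2.0)])


class TestSummaries:
    def test_study_table_row_statistics(self):
        summary, pairs = summarize_measurements(load_observer_table())
        row = format_summary(summary).loc["ANS-Petrous"]
        assert (row["real_mean"], row["real_sd"]) == (48.3, 1.9)
        assert (row["drr_mean"], row["drr_sd"]) == (47.3, 2.1)
        assert row["diff_of_means"] == 1.0
        assert pairs[0] == (pytest.approx(48.25), pytest.approx(47.25))

    def test_constant_row_has_zero_sd(self):
        m = _matrix([[5, 5, 5], [6, 7, 8]], measurements=["a", "a"],
                    modalities=["real", "drr"])
        summary, _ = summarize_measurements(m)
        assert summary.loc["a", "real_sd"] == 0.0

    def test_mean_equals_brute_force_before_rounding(self):
        vals = np.array([[47, 48, 51, 47], [47, 50, 47, 45]], float)
        m = _matrix(vals, measurements=["a", "a"], modalities=["real", "drr"])
        summary, _ = summarize_measurements(m)
        assert summary.loc["a", "real_mean"] == pytest.approx(vals[0].sum() / 4)

    def test_unpaired_measurement_rejected(self):
        m = _matrix([[1, 2], [3, 4], [5, 6]], measurements=["a", "a", "b"],
                    modalities=["real", "drr", "real"])
        with pytest.raises(ValueError, match="missing a modality"):
            summarize_measurements(m)


class TestObserverSimulator:
    def test_zero_noise_reproduces_truth(self):
        truth = [10.2, 20.4, 30.6]
        m = simulate_observers(truth, k=4, sigma_mm=0.0, round_to_mm=False, seed=3)
        np.testing.assert_allclose(m.values, np.tile(np.array(truth)[:, None], (1, 4)))

    def test_zero_noise_with_rounding_snaps_to_whole_mm(self):
        m = simulate_observers([39.6, 41.4], k=4, sigma_mm=0.0, round_to_mm=True, seed=0)
        np.testing.assert_array_equal(m.values, [[40.0] * 4, [41.0] * 4])

    def test_reproducible_per_seed(self):
        a = simulate_observers([10, 20], k=4, sigma_mm=2.0, seed=42)
        b = simulate_observers([10, 20], k=4, sigma_mm=2.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_observers([10, 20], k=4, sigma_mm=2.0, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_unbiased_over_replicates(self):
        # 1000 replicate panels: the mean inter-modality bias should be
        # statistically indistinguishable from zero
        truth = [30.0, 45.0, 60.0, 75.0, 90.0, 105.0]
        biases = []
        for seed in range(1000):
            m = simulate_observers(truth + truth, k=4, sigma_mm=2.0,
                                   round_to_mm=False, seed=seed,
                                   measurements=[f"m{i}" for i in range(6)] * 2,
                                   modalities=["real"] * 6 + ["drr"] * 6)
            _, pairs = summarize_measurements(m)
            biases.append(bland_altman(pairs).bias_mm)
        biases = np.asarray(biases)
        se = biases.std(ddof=1) / np.sqrt(len(biases))
        assert abs(biases.mean()) < 3 * se + 1e-12

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            simulate_observers([1, 2], sigma_mm=-1.0)
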