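import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hypoxsig as hx
from hypoxsig.differential import (DifferentialConfig, ImputationParams,
                                   differential_test, estimate_marker_purity,
                                   filter_valid_values, impute_downshifted)

RAW = DifferentialConfig(apply_filter=False, apply_imputation=False)


def two_group_bundle(a: np.ndarray, b: np.ndarray, ids=None):
    """Wrap two per-group value blocks (proteins x replicates) as a matrix
    plus an oxygen design: group1 = normoxia, group2 = hypoxia."""
    a, b = np.atleast_2d(a).astype(float), np.atleast_2d(b).astype(float)
    ids = ids or [f"P{i}" for i in range(a.shape[0])]
    cols_a = [f"n{j}" for j in range(a.shape[1])]
    cols_b = [f"h{j}" for j in range(b.shape[1])]
    m = hx.IntensityMatrix(pd.DataFrame(np.hstack([a, b]), index=ids,
                                        columns=cols_a + cols_b))
    design = hx.SampleDesign(pd.DataFrame(
        {"subtype": "luminal",
         "oxygen": ["normoxia"] * len(cols_a) + ["hypoxia"] * len(cols_b)},
        index=cols_a + cols_b))
    contrast = hx.Contrast("oxygen", ("normoxia", "hypoxia"))
    return m, design, contrast


class TestFilter:
    def test_fully_observed_matrix_retained(self, secretome_default):
        m, d, _ = hx.simulate_secretome(hx.SecretomeSimConfig(
            n_proteins=50, n_hypoxia_luminal=8, n_hypoxia_basal=4,
            n_hypoxia_shared=2, miss_midpoint=None, seed=1))
        contrast = hx.Contrast("oxygen", ("normoxia", "hypoxia"))
        out = filter_valid_values(m, d, contrast)
        assert out.data.shape == m.data.shape

    def test_half_rule_any_vs_all_groups(self):
        # protein valid in 2/4 of group A and 1/4 of group B
        a = np.array([[1.0, 2.0, np.nan, np.nan]])
        b = np.array([[3.0, np.nan, np.nan, np.nan]])
        m, d, c = two_group_bundle(a, b)
        kept_any = filter_valid_values(m, d, c, DifferentialConfig(
            filter_mode="any_group"))
        kept_all = filter_valid_values(m, d, c, DifferentialConfig(
            filter_mode="all_groups"))
        assert list(kept_any.data.index) == ["P0"]
        assert list(kept_all.data.index) == []

    def test_all_missing_protein_removed_in_both_modes(self):
        a = np.array([[np.nan] * 4, [1.0, 2, 3, 4]])
        b = np.array([[np.nan] * 4, [1.0, 2, 3, 4]])
        m, d, c = two_group_bundle(a, b)
        for mode in ("any_group", "all_groups"):
            out = filter_valid_values(m, d, c,
                                      DifferentialConfig(filter_mode=mode))
            assert list(out.data.index) == ["P1"]

    def test_observed_values_never_altered(self, secretome_default):
        m, d, _ = secretome_default
        contrast = hx.Contrast("oxygen", ("normoxia", "hypoxia"))
        out = filter_valid_values(m, d, contrast)
        pd.testing.assert_frame_equal(out.data, m.data.loc[out.data.index])


class TestImputation:
    def test_no_missing_returns_unchanged(self):
        m = hx.IntensityMatrix(pd.DataFrame(np.arange(12.0).reshape(3, 4)))
        out = impute_downshifted(m, ImputationParams(seed=1))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_observed_entries_unchanged_and_all_missing_filled(self, tiny_matrix):
        out = impute_downshifted(tiny_matrix, ImputationParams(seed=1))
        obs = tiny_matrix.data.notna()
        pd.testing.assert_frame_equal(out.data[obs], tiny_matrix.data[obs])
        assert out.n_missing == 0
        changed = (out.data != tiny_matrix.data) & tiny_matrix.data.isna()
        assert int(changed.sum().sum()) == tiny_matrix.n_missing

    def test_imputed_distribution_matches_downshifted_normal(self):
        """10,000 imputed draws in one column: sample mean and sd within
        3 standard errors of (mean_obs - 1.8*sd_obs, 0.3*sd_obs)."""
        rng = np.random.default_rng(0)
        observed = rng.normal(20.0, 1.0, 50)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = hx.IntensityMatrix(pd.DataFrame({"s1": col}))
        out = impute_downshifted(m, ImputationParams(width=0.3, downshift=1.8,
                                                     seed=5))
        imputed = out.data["s1"].to_numpy()[50:]
        mu, sd = observed.mean(), observed.std(ddof=1)
        target_mean, target_sd = mu - 1.8 * sd, 0.3 * sd
        n = len(imputed)
        assert abs(imputed.mean() - target_mean) < 3 * target_sd / np.sqrt(n)
        assert abs(imputed.std(ddof=1) - target_sd) < 3 * target_sd / np.sqrt(2 * n)

    def test_deterministic_under_seed(self, tiny_matrix):
        a = impute_downshifted(tiny_matrix, ImputationParams(seed=9))
        b = impute_downshifted(tiny_matrix, ImputationParams(seed=9))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_underpopulated_column_error_names_it(self):
        m = hx.IntensityMatrix(pd.DataFrame(
            {"bad": [1.0, np.nan, np.nan], "ok": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="bad"):
            impute_downshifted(m, ImputationParams(seed=0))


class TestTTest:
    def test_identical_groups_null_result(self):
        a = np.array([[1.0, 2, 3]])
        m, d, c = two_group_bundle(a, a)
        t = differential_test(m, d, c, RAW)
        assert t.at["P0", "t_stat"] == 0.0
        assert t.at["P0", "p_value"] == 1.0
        assert t.at["P0", "linear_fold"] == 1.0

    def test_hand_computed_example(self):
        """A={1,2,3} vs B={2,3,4}: pooled t = -1.2247, df 4, p = 0.2879."""
        m, d, c = two_group_bundle(np.array([[1.0, 2, 3]]),
                                   np.array([[2.0, 3, 4]]))
        t = differential_test(m, d, c, RAW)
        assert t.at["P0", "t_stat"] == pytest.approx(-1.224745, abs=1e-4)
        assert t.at["P0", "p_value"] == pytest.approx(0.2879, abs=1e-4)
        assert t.at["P0", "log2fc"] == pytest.approx(1.0)

    def test_matches_first_principles_on_random_matrices(self):
        """Pooled-variance t recomputed from the definition agrees to 1e-9
        on random <=10x8 matrices."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            n_prot = rng.integers(1, 11)
            n1, n2 = rng.integers(2, 5), rng.integers(2, 5)
            a = rng.normal(20, 2, (n_prot, n1))
            b = rng.normal(20, 2, (n_prot, n2))
            m, d, c = two_group_bundle(a, b)
            table = differential_test(m, d, c, RAW)
            for i in range(n_prot):
                m1, m2 = a[i].mean(), b[i].mean()
                sp2 = ((n1 - 1) * a[i].var(ddof=1) + (n2 - 1) * b[i].var(ddof=1)) \
                    / (n1 + n2 - 2)
                t_ref = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
                p_ref = 2 * stats.t.sf(abs(t_ref), n1 + n2 - 2)
                assert table.iloc[i]["t_stat"] == pytest.approx(t_ref, abs=1e-9)
                assert table.iloc[i]["p_value"] == pytest.approx(p_ref, abs=1e-9)

    def test_agrees_with_scipy_ttest_ind(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(6, 5)), rng.normal(size=(6, 4))
        m, d, c = two_group_bundle(a, b)
        table = differential_test(m, d, c, RAW)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(np.abs(table["t_stat"]), np.abs(ref.statistic),
                                   atol=1e-12)
        np.testing.assert_allclose(table["p_value"], ref.pvalue, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_swapping_groups_negates_t_and_log2fc(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        m, d, c = two_group_bundle(a, b)
        fwd = differential_test(m, d, c, RAW)
        m2, d2, c2 = two_group_bundle(b, a)
        rev = differential_test(m2, d2, c2, RAW)
        np.testing.assert_allclose(fwd["t_stat"], -rev["t_stat"], atol=1e-12)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_zero_variance_unequal_means_smallest_p(self):
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            m, d, c = two_group_bundle(np.array([[1.0, 1, 1]]),
                                       np.array([[2.0, 2, 2]]))
            t = differential_test(m, d, c, RAW)
        assert t.at["P0", "p_value"] == np.nextafter(0.0, 1.0)

    def test_type_i_error_calibrated_under_null(self):
        """>=1000 null proteins, no planted effect: rejection rate at
        alpha=0.05 within binomial 3 sigma."""
        m, d, _ = hx.simulate_secretome(hx.SecretomeSimConfig(
            n_proteins=1500, n_hypoxia_luminal=0, n_hypoxia_basal=0,
            n_hypoxia_shared=0, miss_midpoint=None, seed=17))
        c = hx.Contrast("oxygen", ("normoxia", "hypoxia"),
                        {"subtype": "luminal"})
        table = differential_test(m, d, c)
        rate = (table["p_value"] < 0.05).mean()
        sigma = np.sqrt(0.05 * 0.95 / len(table))
        assert abs(rate - 0.05) < 3 * sigma

    def test_planted_effect_detected_with_high_recall(self):
        """Planted 2-log2 effect, 6 vs 6 replicates, noise sd 0.5: planted
        proteins significant at alpha 0.05 with recall >= 0.9."""
        m, d, truth = hx.simulate_secretome(hx.SecretomeSimConfig(
            n_proteins=300, replicates=6, noise_sd=0.5, hypoxia_effect=2.0,
            seed=21))
        c = hx.Contrast("oxygen", ("normoxia", "hypoxia"),
                        {"subtype": "luminal"})
        table = differential_test(m, d, c)
        planted = list(truth.planted["hypoxia_luminal"])
        hits = ((table.loc[planted, "p_value"] < 0.05)
                & (table.loc[planted, "log2fc"] > 0)).mean()
        assert hits >= 0.9


class TestMarkerPurity:
    @staticmethod
    def _pair_matrices(epi_vals, str_vals, marker="KRT8"):
        patients = [f"pt{i}" for i in range(len(epi_vals))]
        epi = hx.IntensityMatrix(pd.DataFrame(
            [epi_vals], index=[marker], columns=[f"{p}_e" for p in patients]))
        stro = hx.IntensityMatrix(pd.DataFrame(
            [str_vals], index=[marker], columns=[f"{p}_s" for p in patients]))
        pairing = {p: (f"{p}_e", f"{p}_s") for p in patients}
        return epi, stro, pairing

    def test_62_fold_excess_gives_1_6_percent(self):
        """Mean epithelium:stroma marker ratio 62 -> 100/62 = 1.6% estimated
        epithelial contamination of stroma."""
        stroma_log2 = [20.0, 21.0, 19.5, 22.0]
        epi_log2 = [v + np.log2(62) for v in stroma_log2]
        epi, stro, pairing = self._pair_matrices(epi_log2, stroma_log2)
        mean_pct, median_pct, per_pt = estimate_marker_purity(
            epi, stro, "KRT8", pairing)
        assert mean_pct == pytest.approx(100 / 62, abs=1e-9)
        assert mean_pct == pytest.approx(1.6, abs=0.05)
        assert median_pct == pytest.approx(100 / 62, abs=1e-9)
        assert len(per_pt) == 4

    def test_equal_intensity_is_100_percent(self):
        epi, stro, pairing = self._pair_matrices([20.0], [20.0])
        mean_pct, _, _ = estimate_marker_purity(epi, stro, "KRT8", pairing)
        assert mean_pct == pytest.approx(100.0)

    def test_zero_stroma_linear_intensity_is_0_percent(self):
        epi, stro, pairing = self._pair_matrices([100.0], [0.0])
        mean_pct, _, _ = estimate_marker_purity(epi, stro, "KRT8", pairing,
                                                input_scale="linear")
        assert mean_pct == 0.0

    def test_zero_epithelium_linear_intensity_is_error(self):
        epi, stro, pairing = self._pair_matrices([0.0], [1.0])
        with pytest.raises(ValueError, match="zero epithelium"):
            estimate_marker_purity(epi, stro, "KRT8", pairing,
                                   input_scale="linear")

    def test_missing_marker_pair_dropped_with_warning(self):
        epi, stro, pairing = self._pair_matrices([20.0, np.nan], [15.0, 15.0])
        with pytest.warns(RuntimeWarning, match="dropped"):
            _, _, per_pt = estimate_marker_purity(epi, stro, "KRT8", pairing)
        assert len(per_pt) == 1
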