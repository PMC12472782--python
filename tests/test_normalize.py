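"""Scaling-factor formulas, stratum behaviour, and the method diagnostic."""

import numpy as np
import pandas as pd
import pytest

from proteopipe import (SimulationConfig, down_scaling_factors, evaluate_normalizations,
                        generate_matrix, housekeeping_factors, mean_based_factors,
                        normalize_matrix, total_count_factors)
from proteopipe.normalize import apply_factors, sample_strata


def matrix_with_totals(totals):
    """Two-protein matrix whose per-sample totals are as given."""
    cols = [f"S{i + 1}" for i in range(len(totals))]
    half = np.array(totals, dtype=float) / 2
    return pd.DataFrame([half, half], index=["A", "B"], columns=cols)


class TestDownScaling:
    def test_factors_forced_by_formula(self):
        m = matrix_with_totals([100, 200, 400])
        f = down_scaling_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 0.5, 0.25])

    def test_per_stratum_minima(self):
        m = matrix_with_totals([100, 200, 300, 600])
        strata = pd.Series(["M", "M", "F", "F"], index=m.columns)
        f = down_scaling_factors(m, strata)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 0.5, 1.0, 0.5])

    def test_equal_totals_identity(self):
        m = matrix_with_totals([100, 100, 100])
        f = down_scaling_factors(m)
        assert (f == 1.0).all()
        pd.testing.assert_frame_equal(apply_factors(m, f), m)

    def test_totals_equal_stratum_minimum_after_scaling(self, study_sized):
        m, ann, _ = study_sized
        result = normalize_matrix(m, ann, method="down_scaling", by_sex=True)
        totals = result.normalized.sum(axis=0)
        for stratum in result.strata.unique():
            sub = totals[result.strata == stratum]
            target = m[result.strata.index[result.strata == stratum]].sum(axis=0).min()
            np.testing.assert_allclose(sub.to_numpy(), target, rtol=1e-9)

    def test_factors_in_unit_interval_with_one_per_stratum(self, study_sized):
        m, ann, _ = study_sized
        result = normalize_matrix(m, ann, method="down_scaling", by_sex=True)
        assert ((result.factors > 0) & (result.factors <= 1)).all()
        for stratum in result.strata.unique():
            assert (result.factors[result.strata == stratum] == 1.0).any()

    def test_zero_total_sample_rejected(self):
        m = matrix_with_totals([100, 0])
        with pytest.raises(ValueError, match="zero-total"):
            down_scaling_factors(m)


class TestOtherFactorSchemes:
    def test_mean_based_formula(self):
        m = pd.DataFrame({"S1": [1.0, 1.0], "S2": [3.0, 3.0]}, index=["A", "B"])
        f = mean_based_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [2.0, 2 / 3])

    def test_mean_based_homogeneity(self, small_matrix):
        f0 = mean_based_factors(small_matrix)
        scaled = small_matrix.copy()
        scaled.iloc[:, 0] *= 5.0
        f1 = mean_based_factors(scaled)
        # scaling one sample by c divides its factor by ~c (up to the grand-mean shift)
        assert f1.iloc[0] < f0.iloc[0]

    def test_total_count_formula_and_equalized_totals(self):
        m = matrix_with_totals([100, 300])
        f = total_count_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [2.0, 2 / 3])
        totals = apply_factors(m, f).sum(axis=0)
        np.testing.assert_allclose(totals.to_numpy(), totals.iloc[0])

    def test_housekeeping_formula(self):
        m = pd.DataFrame({"S1": [10.0, 10.0, 1.0], "S2": [20.0, 20.0, 99.0]},
                         index=["ACTB", "TUBB", "OTHER"])
        f = housekeeping_factors(m, ["ACTB", "TUBB"])
        np.testing.assert_allclose(f.to_numpy(), [1.5, 0.75])

    def test_housekeeping_constant_references_identity(self):
        m = pd.DataFrame({"S1": [10.0, 5.0], "S2": [10.0, 50.0]},
                         index=["ACTB", "OTHER"])
        f = housekeeping_factors(m, ["ACTB"])
        assert (f == 1.0).all()

    def test_absent_reference_named_error(self, small_matrix):
        with pytest.raises(KeyError, match="ACTB"):
            housekeeping_factors(small_matrix, ["ACTB"])


class TestInvariants:
    def test_scale_equivariance_of_all_methods(self, study_sized):
        m, ann, _ = study_sized
        refs = list(m.index[:2])
        for method in ("mean", "down_scaling", "total_count", "housekeeping"):
            r1 = normalize_matrix(m, ann, method=method, reference_ids=refs)
            r2 = normalize_matrix(m * 3.0, ann, method=method, reference_ids=refs)
            pd.testing.assert_series_equal(r1.factors, r2.factors)
            pd.testing.assert_frame_equal(r2.normalized, r1.normalized * 3.0)

    def test_cross_sample_log_ratios_preserved_for_equal_depth(self):
        # two samples in the same stratum with equal totals get equal factors,
        # so their within-protein log-ratios survive down-scaling unchanged
        m = pd.DataFrame({"S1": [1.0, 9.0], "S2": [3.0, 7.0], "S3": [20.0, 20.0]},
                         index=["A", "B"])
        f = down_scaling_factors(m)
        normed = apply_factors(m, f)
        np.testing.assert_allclose(np.log(normed["S1"] / normed["S2"]),
                                   np.log(m["S1"] / m["S2"]))

    def test_missing_values_excluded_from_totals(self):
        m = matrix_with_totals([100, 200])
        m.at["A", "S2"] = np.nan  # S2 total drops to 100
        f = down_scaling_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])


class TestDiagnostics:
    def test_depth_confounding_removed_by_every_scaling_method(self):
        cfg = SimulationConfig(n_proteins=300, n_per_cell=4, depth_sigma=0.3,
                               spike_fraction=0.0, sexes=False, seed=7)
        m, ann, _ = generate_matrix(cfg)
        table = evaluate_normalizations(m, ann)
        assert table.loc["raw", "total_cv"] > 0.05
        for method in ("mean", "down_scaling", "total_count"):
            assert table.loc[method, "total_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_samples_all_methods_tie_at_zero(self, small_annotation):
        col = np.linspace(10, 100, 8)
        m = pd.DataFrame({s: col for s in small_annotation.index},
                         index=[f"P{i}" for i in range(8)])
        table = evaluate_normalizations(m, small_annotation)
        np.testing.assert_allclose(table["total_cv"].to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(table["low_abundance_log2_distortion"].to_numpy(),
                                   0.0, atol=1e-12)

    def test_diagnostic_invariant_under_sample_permutation(self, study_sized):
        m, ann, _ = study_sized
        t1 = evaluate_normalizations(m, ann)
        perm = np.random.default_rng(3).permutation(m.shape[1])
        m2, ann2 = m.iloc[:, perm], ann.iloc[perm]
        t2 = evaluate_normalizations(m2, ann2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_strata_default_to_sex(self, study_sized):
        _, ann, _ = study_sized
        strata = sample_strata(ann, ann.index, by_sex=True)
        assert set(strata) == {"M", "F"}
        assert (sample_strata(ann, ann.index, by_sex=False) == "all").all()
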