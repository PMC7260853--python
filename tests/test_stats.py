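import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cordmap.stats import (
    SingularCovarianceError,
    axis_annotation,
    calibration_sim,
    count_analysis,
    hotelling_t2,
    permutation_hotelling,
    star_string,
)
from cordmap.synthetic import ClusterSpec, CohortConfig, EffectSpec

from conftest import HOTELLING_FIXTURE
from oracles import hotelling_oracle, t_test_oracle


class TestHotelling:
    def test_frozen_oracle_fixture(self):
        res = hotelling_t2(HOTELLING_FIXTURE["x1"], HOTELLING_FIXTURE["x2"])
        assert res.t2 == pytest.approx(HOTELLING_FIXTURE["t2"], abs=1e-8)
        assert res.f_stat == pytest.approx(HOTELLING_FIXTURE["f_stat"], abs=1e-8)
        assert (res.df1, res.df2) == (HOTELLING_FIXTURE["df1"], HOTELLING_FIXTURE["df2"])
        assert res.p_value == pytest.approx(HOTELLING_FIXTURE["p_value"], abs=1e-8)

    def test_runtime_oracle_agreement(self, rng):
        for _ in range(10):
            x1 = rng.normal(0.5, 0.1, size=(8, 2))
            x2 = rng.normal(0.5, 0.1, size=(6, 2))
            t2, f, df1, df2, p = hotelling_oracle(x1.tolist(), x2.tolist())
            res = hotelling_t2(x1, x2)
            assert res.t2 == pytest.approx(t2, abs=1e-8)
            assert res.f_stat == pytest.approx(f, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        res = hotelling_t2(x, x.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert all(f.stars == "" for f in res.axis_flags)

    def test_1d_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(0.3, 1.2, size=rng.integers(5, 30))
            res = hotelling_t2(a, b, annotate_axes=False)
            t, p = sps.ttest_ind(a, b)  # pooled-variance two-sided
            assert res.t2 == pytest.approx(t * t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_mahalanobis_identity(self, rng):
        x1 = rng.normal(size=(12, 2))
        x2 = rng.normal(0.2, 1.0, size=(15, 2))
        res = hotelling_t2(x1, x2, annotate_axes=False)
        n1, n2 = len(x1), len(x2)
        s = ((n1 - 1) * np.cov(x1.T) + (n2 - 1) * np.cov(x2.T)) / (n1 + n2 - 2)
        from scipy.spatial.distance import mahalanobis

        d2 = mahalanobis(x1.mean(0), x2.mean(0), np.linalg.inv(s)) ** 2
        assert res.t2 == pytest.approx(n1 * n2 / (n1 + n2) * d2, rel=1e-8)

    def test_affine_invariance(self, rng):
        x1 = rng.normal(size=(20, 2))
        x2 = rng.normal(0.5, 1.0, size=(25, 2))
        a = np.array([[2.0, 0.3], [-0.5, 1.5]])
        b = np.array([3.0, -1.0])
        ref = hotelling_t2(x1, x2, annotate_axes=False)
        moved = hotelling_t2(x1 @ a.T + b, x2 @ a.T + b, annotate_axes=False)
        assert moved.t2 == pytest.approx(ref.t2, abs=1e-8)
        assert moved.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_chi2_variant(self, rng):
        x1 = rng.normal(size=(200, 2))
        x2 = rng.normal(0.05, 1.0, size=(200, 2))
        f_res = hotelling_t2(x1, x2, method="f", annotate_axes=False)
        c_res = hotelling_t2(x1, x2, method="chi2", annotate_axes=False)
        assert c_res.p_value == pytest.approx(sps.chi2.sf(c_res.t2, 2))
        # large-sample: the two p-values are close
        assert abs(f_res.p_value - c_res.p_value) < 0.01

    def test_singular_covariance_raises(self):
        x1 = np.column_stack([np.arange(5.0), np.arange(5.0)])  # perfectly collinear
        x2 = np.column_stack([np.arange(5.0), np.arange(5.0)]) + 0.5
        with pytest.raises(SingularCovarianceError, match="permutation"):
            hotelling_t2(x1, x2)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="n1"):
            hotelling_t2(np.zeros((1, 2)), np.ones((5, 2)))

    def test_pooled_sample_input(self, small_cohort_norm):
        from cordmap.geometry import pool_sections

        s1 = pool_sections(small_cohort_norm, "M1", "control")
        s2 = pool_sections(small_cohort_norm, "M1", "mutant")
        res = hotelling_t2(s1, s2)
        assert res.n1 == s1.n and res.n2 == s2.n


class TestPermutation:
    def test_identical_samples_p_one(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        assert permutation_hotelling(x, x.copy(), n_perm=199, seed=0) == 1.0

    def test_determinism(self, rng):
        x1 = rng.normal(size=(15, 2))
        x2 = rng.normal(0.3, 1.0, size=(15, 2))
        p1 = permutation_hotelling(x1, x2, n_perm=199, seed=7)
        p2 = permutation_hotelling(x1, x2, n_perm=199, seed=7)
        assert p1 == p2

    def test_add_one_estimator_bounds(self, rng):
        x1 = rng.normal(size=(10, 2))
        x2 = rng.normal(3.0, 1.0, size=(10, 2))  # huge separation
        p = permutation_hotelling(x1, x2, n_perm=99, seed=1)
        assert p == pytest.approx(1.0 / 100.0)  # never exactly 0

    def test_min_permutations_enforced(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_hotelling(x, x, n_perm=10)

    def test_singular_fallback(self):
        # collinear data: parametric refuses, permutation still works
        x1 = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        x2 = x1 + np.array([1.0, 2.0])
        p = permutation_hotelling(x1, x2, n_perm=199, seed=0)
        assert 0.0 < p <= 1.0

    def test_agrees_with_parametric_under_null(self, rng):
        diffs = []
        for _ in range(20):
            x1 = rng.normal(size=(50, 2))
            x2 = rng.normal(size=(50, 2))
            p_f = hotelling_t2(x1, x2, annotate_axes=False).p_value
            p_perm = permutation_hotelling(x1, x2, n_perm=299, seed=rng)
            diffs.append(abs(p_f - p_perm))
        assert np.median(diffs) <= 0.05


class TestAxisAnnotation:
    def test_identical_no_flags(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        flags = axis_annotation(x, x.copy())
        assert [f.stars for f in flags] == ["", ""]
        assert [f.axis for f in flags] == ["ML_x", "DV_y"]

    def test_matches_reference_t(self, rng):
        x1 = rng.normal(size=(30, 2))
        x2 = rng.normal(0.4, 1.0, size=(25, 2))
        flags = axis_annotation(x1, x2)
        for axis, flag in enumerate(flags):
            t, p = sps.ttest_ind(x1[:, axis], x2[:, axis])
            assert flag.t_stat == pytest.approx(t, rel=1e-10)
            assert flag.p_value == pytest.approx(p, rel=1e-10)

    def test_zero_variance_equal_means(self):
        x = np.full((5, 2), 0.5)
        flags = axis_annotation(x, x.copy())
        assert all(f.p_value == 1.0 for f in flags)

    def test_zero_variance_unequal_means(self):
        x1 = np.full((5, 2), 0.5)
        x2 = np.full((5, 2), 0.7)
        with pytest.warns(UserWarning, match="zero variance"):
            flags = axis_annotation(x1, x2)
        assert all(f.p_value == 0.0 for f in flags)

    def test_dv_shift_flags_dv_only(self, rng):
        # power on the shifted axis, ~alpha on the untouched axis
        dv_hits = ml_hits = 0
        reps = 100
        for _ in range(reps):
            x1 = rng.normal(0.5, 0.1, size=(200, 2))
            x2 = rng.normal(0.5, 0.1, size=(200, 2))
            x2[:, 1] -= 0.05
            flags = axis_annotation(x1, x2)
            ml_hits += flags[0].p_value < 0.05
            dv_hits += flags[1].p_value < 0.05
        assert dv_hits / reps > 0.9
        assert ml_hits / reps < 0.15

    def test_star_thresholds(self):
        assert star_string(0.04) == "*"
        assert star_string(0.009) == "**"
        assert star_string(0.0009) == "***"
        assert star_string(0.06) == ""
        assert star_string(0.004, levels=((0.005, "**"), (0.05, "*"))) == "**"


def _count_df(control_means, mutant_means, marker="M1"):
    """Build a cell table whose per-animal per-section counts are given."""
    rows = []
    for genotype, per_animal in (("control", control_means), ("mutant", mutant_means)):
        for a, sections in enumerate(per_animal):
            for s, count in enumerate(sections):
                for _ in range(count):
                    rows.append(
                        {
                            "animal_id": f"{genotype}_{a}",
                            "genotype": genotype,
                            "section_id": f"{genotype}_{a}_s{s}",
                            "marker": marker,
                            "x_norm": 0.5,
                            "y_norm": 0.5,
                        }
                    )
    return pd.DataFrame(rows)


class TestCountAnalysis:
    # hand oracle: per-animal means {10,12,14} vs {6,8,10} ->
    # t = sqrt(6), df = 4 (values frozen from tests/oracles.py)
    ORACLE_T = 2.449489742783178
    ORACLE_P_TWO = 0.07048399691022003
    ORACLE_P_GREATER = 0.035241998455110016

    @pytest.fixture
    def oracle_df(self):
        # 4 equal sections per animal -> per-animal means are exact
        return _count_df(
            [[10] * 4, [12] * 4, [14] * 4],
            [[6] * 4, [8] * 4, [10] * 4],
        )

    def test_hand_oracle_two_sided(self, oracle_df):
        res = count_analysis(oracle_df, "M1")
        assert res.t_stat == pytest.approx(self.ORACLE_T, abs=1e-10)
        assert res.df == 4
        assert res.p_value == pytest.approx(self.ORACLE_P_TWO, abs=1e-10)
        assert res.group_means == {"control": 12.0, "mutant": 8.0}

    def test_one_tailed_is_half_two_tailed(self, oracle_df):
        res = count_analysis(oracle_df, "M1", tails="greater")
        assert res.p_value == pytest.approx(self.ORACLE_P_GREATER, abs=1e-10)
        assert res.p_value == pytest.approx(self.ORACLE_P_TWO / 2, abs=1e-12)

    def test_matches_independent_oracle(self, oracle_df):
        t, df, p = t_test_oracle([10, 12, 14], [6, 8, 10])
        res = count_analysis(oracle_df, "M1")
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_all_equal_counts(self):
        df = _count_df([[5] * 4] * 3, [[5] * 4] * 3)
        res = count_analysis(df, "M1")
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_sem_definition(self, oracle_df):
        res = count_analysis(oracle_df, "M1")
        assert res.group_sems["control"] == pytest.approx(
            np.std([10, 12, 14], ddof=1) / np.sqrt(3)
        )

    def test_too_few_animals(self):
        df = _count_df([[5] * 4], [[5] * 4] * 3)
        with pytest.raises(ValueError, match="fewer than 2 animals"):
            count_analysis(df, "M1")

    def test_warns_below_four_sections(self):
        df = _count_df([[5] * 2] * 3, [[5] * 4] * 3)
        with pytest.warns(UserWarning, match="fewer than 4 sections"):
            count_analysis(df, "M1")

    def test_sections_inventory_credits_zero_sections(self):
        df = _count_df([[10] * 4] * 2, [[10] * 4] * 2)
        inventory = df[["genotype", "animal_id", "section_id"]].drop_duplicates()
        # add an extra all-zero section for one control animal
        extra = pd.DataFrame(
            [{"genotype": "control", "animal_id": "control_0",
              "section_id": "control_0_s_extra"}]
        )
        inventory = pd.concat([inventory, extra], ignore_index=True)
        res = count_analysis(df, "M1", sections=inventory)
        assert res.per_animal_means["control"]["control_0"] == pytest.approx(8.0)


class TestCalibrationSim:
    def test_null_rejection_near_alpha(self):
        cfg = CohortConfig(animal_effect_sd=0.0, seed=0)
        table = calibration_sim(
            {"null": cfg}, n_reps=300, alpha=0.05, seed=4, units=("cells",)
        )
        rate = table.loc[table["unit"] == "cells", "rejection_rate"].iloc[0]
        # wide 99% band for 300 reps
        assert 0.02 <= rate <= 0.09

    def test_power_increases_with_shift(self):
        grid = {
            f"shift_{s}": CohortConfig(
                effect=EffectSpec(shift=(0.0, -s)),
                animal_effect_sd=0.0,
                mixture=(ClusterSpec(center=(0.5, 0.55), sd=(0.1, 0.1)),),
            )
            for s in (0.0, 0.03, 0.08)
        }
        table = calibration_sim(grid, n_reps=60, alpha=0.05, seed=5, units=("cells",))
        rates = table.set_index("setting")["rejection_rate"]
        assert rates["shift_0.08"] >= rates["shift_0.0"]
        assert rates["shift_0.08"] > 0.8

    def test_count_effect_does_not_trigger_positional(self):
        cfg = CohortConfig(
            effect=EffectSpec(count_ratio=0.5), animal_effect_sd=0.0, seed=0
        )
        table = calibration_sim(
            {"count_only": cfg}, n_reps=300, alpha=0.05, seed=6, units=("cells",)
        )
        rate = table["rejection_rate"].iloc[0]
        assert 0.02 <= rate <= 0.09

    def test_animal_unit_rows_present(self):
        cfg = CohortConfig(animal_effect_sd=0.0)
        table = calibration_sim({"null": cfg}, n_reps=20, seed=7)
        assert set(table["unit"]) == {"cells", "animals"}
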