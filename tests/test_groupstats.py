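"""Outlier masking, ANOVA, protected LSD and FDR, against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rescuescreen import (
    AnalysisConfig,
    anova_one_way,
    estimate_fdr,
    mask_outliers,
    plsd_contrasts,
    screen_study,
)
from rescuescreen.groupstats import screen_arrays
from rescuescreen.groupstats import test_gene as run_single_gene

from conftest import make_study

FOUR = {"YC": [1, 2, 3], "AC": [2, 3, 4], "ST": [3, 4, 5], "LT": [4, 5, 6]}


class TestMaskOutliers:
    def test_single_extreme_point_is_masked(self):
        # mean 25, sample SD sqrt(1350)=36.742; |100-25|=75 > 2*36.742
        masked, report = mask_outliers({"g": [10, 10, 10, 10, 10, 100]})
        assert np.isnan(masked["g"][5])
        assert (masked["g"][:5] == 10).all()
        assert report.n_masked["g"] == 1

    def test_constant_group_masks_nothing(self):
        masked, report = mask_outliers({"g": [7.0] * 6})
        assert not np.isnan(masked["g"]).any()
        assert report.total_masked == 0

    def test_moderate_spread_masks_nothing(self):
        # max deviation 2.5 < 2 * SD (= 2 * 1.8708)
        masked, report = mask_outliers({"g": [1, 2, 3, 4, 5, 6]})
        assert report.total_masked == 0

    def test_single_pass_not_reiterated(self):
        vals = [10.0, 10, 10, 10, 10, 100]
        once, _ = mask_outliers({"g": vals})
        again, rep = mask_outliers({"g": once["g"]})
        assert rep.total_masked == 0  # survivors are never re-screened

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=12))
    def test_masking_never_increases_group_sd(self, vals):
        masked, _ = mask_outliers({"g": vals})
        kept = masked["g"][~np.isnan(masked["g"])]
        if len(kept) >= 2:
            assert np.std(kept, ddof=1) <= np.std(vals, ddof=1) + 1e-12


class TestAnova:
    def test_hand_decomposition_example(self):
        res = anova_one_way(FOUR)
        assert res.f == pytest.approx(5.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (3, 8)
        assert res.p == pytest.approx(stats.f.sf(5.0, 3, 8), rel=1e-12)
        assert res.p == pytest.approx(0.030578, abs=1e-6)
        assert res.mse == pytest.approx(1.0)

    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_one_way({g: [5.0, 6.0, 7.0] for g in ("YC", "AC", "ST", "LT")})
        assert res.f == 0.0
        assert res.p == 1.0

    def test_two_group_reduction_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = anova_one_way({"YC": a, "AC": b})
        t, p = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_zero_variance_unequal_means_is_degenerate(self):
        res = anova_one_way({"YC": [1.0, 1.0], "AC": [2.0, 2.0]})
        assert res.degenerate and res.p == 0.0 and np.isinf(res.f)

    def test_fewer_than_two_groups_untestable(self):
        with pytest.raises(ValueError, match="untestable"):
            anova_one_way({"YC": [1.0, 2.0], "AC": [np.nan, 1.0]})


class TestPlsd:
    def test_hand_contrast_example(self):
        res = anova_one_way(FOUR)
        contrasts = plsd_contrasts(res)
        yc_ac = contrasts[0]
        assert yc_ac.pair == ("YC", "AC")
        assert yc_ac.difference == pytest.approx(-1.0)
        assert yc_ac.t == pytest.approx(-1.0 / np.sqrt(2 / 3), rel=1e-12)
        assert yc_ac.p == pytest.approx(2 * stats.t.sf(np.sqrt(1.5), 8), rel=1e-12)
        assert yc_ac.p == pytest.approx(0.255508, abs=1e-6)
        assert not yc_ac.significant  # contrast p > alpha despite ANOVA p <= alpha

    def test_identical_means_give_t_zero_p_one(self):
        res = anova_one_way({
            "YC": [1.0, 2, 3], "AC": [1.0, 2, 3], "ST": [0.0, 2, 4], "LT": [1.0, 1, 4],
        })
        c = plsd_contrasts(res)[0]
        assert c.t == 0.0 and c.p == 1.0

    def test_protection_blocks_significance_when_anova_not_significant(self, rng):
        # small uniform shift: contrast p can dip under alpha while ANOVA p > alpha
        found = False
        for seed in range(40):
            r = np.random.default_rng(seed)
            groups = {g: r.normal(0, 1, 6) for g in ("YC", "AC", "ST", "LT")}
            res = anova_one_way(groups)
            if res.p > 0.05:
                for c in plsd_contrasts(res):
                    assert not c.significant
                    if c.p <= 0.05:
                        found = True
        assert found  # the protection rule actually bit at least once


class TestFdr:
    @pytest.mark.parametrize(
        "n_tested, n_sig, expected",
        [(14828, 3502, 0.05 * 14828 / 3502), (1000, 50, 1.0)],
    )
    def test_ratio_definition(self, n_tested, n_sig, expected):
        assert estimate_fdr(n_tested, n_sig, 0.05) == pytest.approx(expected)

    def test_zero_significant_is_not_applicable(self):
        assert np.isnan(estimate_fdr(1000, 0, 0.05))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr(10, 11, 0.05)


class TestVectorizedScreen:
    def test_matches_scalar_path_gene_by_gene(self, rng):
        vals = rng.lognormal(5, 1, size=(50, 24))
        vals[rng.uniform(size=vals.shape) < 0.05] = np.nan
        vals = np.where(np.isnan(vals), np.nan, np.maximum(vals, 1e-3))
        study = make_study(vals)
        df = screen_study(study)
        cols = study.group_columns()
        for i, gid in enumerate(study.gene_ids):
            per_group = {g: study.values.loc[gid, cs].to_numpy() for g, cs in cols.items()}
            scalar = run_single_gene(gid, per_group)
            row = df.iloc[i]
            if scalar.untestable:
                assert row["untestable"]
                continue
            assert row["f"] == pytest.approx(scalar.anova.f, rel=1e-10)
            assert row["p"] == pytest.approx(scalar.anova.p, rel=1e-10)
            assert row["mse"] == pytest.approx(scalar.anova.mse, rel=1e-10)
            for c in scalar.contrasts:
                key = f"{c.pair[0]}_{c.pair[1]}"
                assert row[f"t_{key}"] == pytest.approx(c.t, rel=1e-10)
                assert row[f"p_{key}"] == pytest.approx(c.p, rel=1e-10)
                assert bool(row[f"sig_{key}"]) == c.significant

    def test_group_with_too_few_values_is_untestable(self):
        vals = np.full((1, 24), 50.0)
        vals[0, 6:11] = np.nan  # AC left with a single value
        df = screen_study(make_study(vals))
        assert bool(df.loc[0, "untestable"])

    def test_null_calibration_of_anova_and_contrasts(self, rng):
        # 10,000 null genes: ANOVA and each unprotected contrast reject at
        # ~alpha; the protected YC-AC contrast rejects well below alpha
        G = 10_000
        vals = rng.standard_normal((G, 24))
        cols = {g: np.arange(i * 6, (i + 1) * 6) for i, g in enumerate(("YC", "AC", "ST", "LT"))}
        res = screen_arrays(vals, cols, AnalysisConfig(), apply_masking=False)
        se3 = 3 * np.sqrt(0.05 * 0.95 / G)
        assert abs((res["p"] <= 0.05).mean() - 0.05) < se3
        for key in ("YC_AC", "LT_AC", "ST_AC"):
            assert abs((res[f"p_{key}"] <= 0.05).mean() - 0.05) < se3
            assert res[f"sig_{key}"].mean() < 0.05  # protection strictly below alpha
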