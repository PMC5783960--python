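"""Template assignment rules and screen-level concordance/overlap summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rescuescreen import (
    AnalysisConfig,
    TemplateLabel,
    assign_template,
    classify,
    concordance_stats,
    overlap_enrichment,
    summarize_classification,
)
from rescuescreen.groupstats import AnovaResult, ContrastResult, GeneTestResult


def _result(anova_p, yc, ac, st, lt, p_yc_ac, p_st, p_lt, mse=25.0, n=6):
    """Build a GeneTestResult from group means and contrast p-values."""
    means = {"YC": yc, "AC": ac, "ST": st, "LT": lt}
    anova = AnovaResult(
        f=1.0, p=anova_p, mse=mse, df_between=3, df_within=20,
        means=means, sems={g: 1.0 for g in means}, ns={g: n for g in means},
    )
    contrasts = [
        ContrastResult(("YC", "AC"), yc - ac, 0.0, p_yc_ac,
                       p_yc_ac <= 0.05 and anova_p <= 0.05),
        ContrastResult(("LT", "AC"), lt - ac, 0.0, p_lt,
                       p_lt <= 0.05 and anova_p <= 0.05),
        ContrastResult(("ST", "AC"), st - ac, 0.0, p_st,
                       p_st <= 0.05 and anova_p <= 0.05),
    ]
    return GeneTestResult(gene_id="g", anova=anova, contrasts=contrasts)


@pytest.mark.parametrize(
    "kwargs, expected_label, expected_dir",
    [
        # aging down, LT significantly up -> countered (II)
        (dict(anova_p=.01, yc=100, ac=80, st=85, lt=95, p_yc_ac=.01, p_st=.30, p_lt=.02),
         TemplateLabel.II, -1),
        # aging up, no significant arm -> unchanged (III)
        (dict(anova_p=.01, yc=100, ac=130, st=128, lt=131, p_yc_ac=.01, p_st=.5, p_lt=.4),
         TemplateLabel.III, 1),
        # aging down, ST significantly further down -> exacerbated
        (dict(anova_p=.01, yc=100, ac=80, st=60, lt=79, p_yc_ac=.01, p_st=.01, p_lt=.9),
         TemplateLabel.ANOMALOUS, -1),
        # conflicting arms (one countered, one exacerbated) -> ANOMALOUS
        (dict(anova_p=.01, yc=100, ac=80, st=60, lt=95, p_yc_ac=.01, p_st=.01, p_lt=.01),
         TemplateLabel.ANOMALOUS, -1),
        # aging up with both arms significantly down -> countered (IV)
        (dict(anova_p=.01, yc=100, ac=130, st=105, lt=102, p_yc_ac=.01, p_st=.01, p_lt=.01),
         TemplateLabel.IV, 1),
        # aging down, no arm -> I
        (dict(anova_p=.01, yc=100, ac=80, st=81, lt=82, p_yc_ac=.01, p_st=.6, p_lt=.6),
         TemplateLabel.I, -1),
        # YC-AC contrast not significant -> NOT_AGING
        (dict(anova_p=.01, yc=100, ac=98, st=80, lt=80, p_yc_ac=.40, p_st=.01, p_lt=.01),
         TemplateLabel.NOT_AGING, 0),
        # omnibus not significant -> NOT_SIGNIFICANT even with small contrast p
        (dict(anova_p=.20, yc=100, ac=80, st=95, lt=95, p_yc_ac=.01, p_st=.01, p_lt=.01),
         TemplateLabel.NOT_SIGNIFICANT, 0),
    ],
    ids=["II", "III", "anomalous", "conflict", "IV", "I", "not-aging", "not-significant"],
)
def test_assign_template_rules(kwargs, expected_label, expected_dir):
    label, aging_dir, arms = assign_template(_result(**kwargs))
    assert label is expected_label
    assert aging_dir == expected_dir
    if label in (TemplateLabel.I, TemplateLabel.III):
        assert arms == {}


def test_classify_agrees_with_scalar_assignment(planted_run):
    config = AnalysisConfig()
    stats_df, class_df = planted_run["stats"], planted_run["classes"]
    # spot-check 200 genes through the scalar rule path
    for i in range(0, len(stats_df), max(len(stats_df) // 200, 1)):
        row = stats_df.iloc[i]
        means = {g: row[f"mean_{g}"] for g in ("YC", "AC", "ST", "LT")}
        anova = AnovaResult(
            f=row["f"], p=row["p"], mse=row["mse"], df_between=3,
            df_within=int(row["df_within"]), means=means, sems={},
            ns={g: int(row[f"n_{g}"]) for g in means},
        )
        contrasts = [
            ContrastResult(pair, row[f"diff_{pair[0]}_{pair[1]}"], 0.0,
                           row[f"p_{pair[0]}_{pair[1]}"],
                           bool(row[f"sig_{pair[0]}_{pair[1]}"]))
            for pair in (("YC", "AC"), ("LT", "AC"), ("ST", "AC"))
        ]
        res = GeneTestResult(gene_id=row["gene_id"], anova=anova,
                             contrasts=contrasts, untestable=bool(row["untestable"]))
        label, _, _ = assign_template(res, config)
        assert class_df.iloc[i]["label"] == label.value


def test_labels_partition_all_genes(planted_run):
    class_df = planted_run["classes"]
    summary = summarize_classification(class_df)
    assert sum(summary.counts.values()) == len(class_df)
    assert class_df["label"].isin([l.value for l in TemplateLabel]).all()


def test_direction_consistency_of_templates(planted_run):
    df = planted_run["classes"].merge(planted_run["stats"], on="gene_id")
    ii = df[df["label"] == "II"]
    iv = df[df["label"] == "IV"]
    # template II: aging down (AC < YC); template IV: aging up (AC > YC)
    assert (ii["mean_AC"] < ii["mean_YC"]).all()
    assert (iv["mean_AC"] > iv["mean_YC"]).all()
    sens = df[df["label"].isin(["II", "IV"])]
    assert ((sens["ST_significant"]) | (sens["LT_significant"])).all()


def test_arm_bookkeeping_matches_printed_convention():
    # LT-only=517, ST-only=193, both=166 -> totals 683/359, sensitive 876
    labels = (["II"] * (517 + 193 + 166)) + ["I"] * 10
    st_sig = [False] * 517 + [True] * (193 + 166) + [False] * 10
    lt_sig = [True] * 517 + [False] * 193 + [True] * 166 + [False] * 10
    class_df = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(labels))],
        "label": labels,
        "aging_direction": -1,
        "ST_direction": 0, "ST_significant": st_sig,
        "LT_direction": 0, "LT_significant": lt_sig,
    })
    s = summarize_classification(class_df)
    assert (s.n_lt_only, s.n_st_only, s.n_both) == (517, 193, 166)
    assert (s.n_lt_total, s.n_st_total) == (683, 359)
    assert s.n_sensitive == 876


class TestConcordance:
    def test_all_same_direction_closed_form(self):
        n = 12
        df = pd.DataFrame({
            "mean_AC": np.full(n, 100.0),
            "mean_ST": np.linspace(110, 150, n),
            "mean_LT": np.linspace(105, 160, n),
        })
        c = concordance_stats(df)
        assert c.concordance_fraction == 1.0
        assert c.binomial_p_direction == pytest.approx(0.5 ** n, rel=1e-12)

    def test_identical_arms_give_r_one(self, rng):
        ac = rng.uniform(50, 200, 30)
        arm = ac * rng.uniform(0.5, 2.0, 30)
        df = pd.DataFrame({"mean_AC": ac, "mean_ST": arm, "mean_LT": arm})
        c = concordance_stats(df)
        assert c.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert c.concordance_fraction == 1.0

    def test_pearson_matches_numpy_oracle(self, rng):
        ac = rng.uniform(50, 200, 40)
        st = ac * np.exp(rng.normal(0, 0.3, 40))
        lt = ac * np.exp(rng.normal(0, 0.3, 40))
        c = concordance_stats(pd.DataFrame({"mean_AC": ac, "mean_ST": st, "mean_LT": lt}))
        r_oracle = np.corrcoef(np.log2(lt / ac), np.log2(st / ac))[0, 1]
        assert c.pearson_r == pytest.approx(r_oracle, rel=1e-12)

    def test_printed_concordance_fraction_and_tail(self):
        # 822 of 876 concordant: fraction 93.8..., binomial tail < 1e-12
        p = stats.binomtest(822, 876, 0.5, alternative="greater").pvalue
        assert 822 / 876 == pytest.approx(0.93835, abs=1e-5)
        assert p < 1e-12

    def test_zero_arm_difference_excluded(self):
        df = pd.DataFrame({
            "mean_AC": [100.0, 100.0], "mean_ST": [100.0, 110.0],
            "mean_LT": [120.0, 115.0],
        })
        c = concordance_stats(df)
        assert c.n_zero_diff_excluded == 1
        assert c.n_compared == 1


class TestOverlap:
    def test_printed_arm_counts_arithmetic(self):
        res = overlap_enrichment(359, 683, 166, 2342)
        assert res.expected_both == pytest.approx(359 * 683 / 2342, rel=1e-12)
        assert res.expected_both == pytest.approx(104.7, abs=0.05)
        assert res.fold == pytest.approx(166 / (359 * 683 / 2342), rel=1e-12)
        assert res.binomial_p < 1e-6

    def test_binomial_tail_matches_enumeration(self):
        res = overlap_enrichment(10, 10, 0, 100)
        assert res.expected_both == pytest.approx(1.0)
        assert res.binomial_p == pytest.approx(1.0)
        res2 = overlap_enrichment(10, 10, 3, 100)
        # direct enumeration of the upper binomial tail at p0 = 0.01
        k = np.arange(3, 101)
        oracle = float(np.sum(stats.binom.pmf(k, 100, 0.01)))
        assert res2.binomial_p == pytest.approx(oracle, rel=1e-10)

    def test_degenerate_full_overlap(self):
        res = overlap_enrichment(7, 7, 7, 7)
        assert res.expected_both == pytest.approx(7.0)
        assert res.fold == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(10, 5, 6, 100)
        with pytest.raises(ValueError):
            overlap_enrichment(10, 10, 0, 0)
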