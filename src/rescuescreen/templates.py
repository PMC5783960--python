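"""Expression-template classification of aging-dependent genes.

A gene enters classification when its omnibus ANOVA is significant and its
protected YC-AC contrast is significant (an "aging-dependent" gene, with
aging direction = sign of AC mean - YC mean).  Rescue arms (ST-AC, LT-AC
protected contrasts) then decide the template:

* no significant arm            -> template I (aging down) or III (aging up)
* every significant arm opposite
  to the aging direction        -> template II (aging down) or IV (aging up)
* any significant arm in the
  aging direction               -> ANOMALOUS (the rescue exacerbates, or the
                                   arms conflict)

Screen-level summaries recompute the bookkeeping of such a screen: arm
totals (ST-only / LT-only / both), direction concordance between the two
rescue arms with an exact binomial test, the Pearson correlation of the
arms' log2 fold changes vs AC, and the chance-expected ST/LT list overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import AnalysisConfig, GeneTestResult


class TemplateLabel(str, Enum):
    I = "I"                             # aging down, rescue unchanged
    II = "II"                           # aging down, rescue up (countered)
    III = "III"                         # aging up, rescue unchanged
    IV = "IV"                           # aging up, rescue down (countered)
    ANOMALOUS = "ANOMALOUS"             # rescue moves with aging (exacerbated)
    NOT_AGING = "NOT_AGING"             # ANOVA-significant, YC-AC not significant
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT" # omnibus ANOVA p > alpha
    UNTESTABLE = "UNTESTABLE"

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.value


TEMPLATES: tuple[TemplateLabel, ...] = (
    TemplateLabel.I, TemplateLabel.II, TemplateLabel.III, TemplateLabel.IV,
)
SENSITIVE_LABELS: tuple[TemplateLabel, ...] = (
    TemplateLabel.II, TemplateLabel.IV, TemplateLabel.ANOMALOUS,
)


@dataclass
class ClassificationSummary:
    """Label counts plus the arm bookkeeping of the screen."""

    counts: dict[str, int]
    n_tested: int
    n_aging_dependent: int
    n_sensitive: int          # II + IV + ANOMALOUS (any significant arm)
    n_countered: int          # II + IV
    n_unchanged: int          # I + III
    n_st_only: int
    n_lt_only: int
    n_both: int

    @property
    def n_st_total(self) -> int:
        return self.n_st_only + self.n_both

    @property
    def n_lt_total(self) -> int:
        return self.n_lt_only + self.n_both


@dataclass
class ConcordanceSummary:
    n_sensitive: int
    n_compared: int
    n_same_direction: int
    n_zero_diff_excluded: int
    concordance_fraction: float
    binomial_p_direction: float
    pearson_r: float


@dataclass
class OverlapResult:
    n_st_total: int
    n_lt_total: int
    n_both: int
    n_universe: int
    expected_both: float
    fold: float
    binomial_p: float


# ---------------------------------------------------------------------------
# Per-gene assignment
# ---------------------------------------------------------------------------

def assign_template(result: GeneTestResult, config: AnalysisConfig = AnalysisConfig()):
    """Assign one gene's template from its protected contrasts.

    Returns ``(label, aging_direction, arm_directions)`` where
    ``arm_directions`` maps each significant rescue arm (``"ST"``/``"LT"``)
    to the sign of (arm mean - AC mean).
    """
    if result.untestable:
        return TemplateLabel.UNTESTABLE, 0, {}
    if result.anova.p > config.alpha:
        return TemplateLabel.NOT_SIGNIFICANT, 0, {}
    by_pair = {c.pair: c for c in result.contrasts}
    aging = by_pair[("YC", "AC")]
    if not aging.significant:
        return TemplateLabel.NOT_AGING, 0, {}
    # contrast difference is YC - AC; aging direction is AC - YC
    aging_dir = int(np.sign(-aging.difference))
    arms: dict[str, int] = {}
    for arm in ("ST", "LT"):
        c = by_pair.get((arm, "AC"))
        if c is not None and c.significant:
            arms[arm] = int(np.sign(c.difference))
    if not arms:
        label = TemplateLabel.I if aging_dir < 0 else TemplateLabel.III
    elif any(d == aging_dir for d in arms.values()):
        label = TemplateLabel.ANOMALOUS
    else:
        label = TemplateLabel.II if aging_dir < 0 else TemplateLabel.IV
    return label, aging_dir, arms


def classify(stats_df: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Vectorized template assignment over a screen result table.

    Expects the columns produced by :func:`rescuescreen.groupstats.screen_study`.
    Returns one row per gene: label, aging_direction, per-arm direction and
    significance flags.
    """
    n = len(stats_df)
    untestable = stats_df["untestable"].to_numpy(bool)
    p = stats_df["p"].to_numpy(float)
    anova_sig = ~untestable & (p <= config.alpha)
    aging_sig = stats_df["sig_YC_AC"].to_numpy(bool)
    aging_dir = np.sign(-stats_df["diff_YC_AC"].to_numpy(float)).astype(int)
    st_sig = stats_df["sig_ST_AC"].to_numpy(bool)
    lt_sig = stats_df["sig_LT_AC"].to_numpy(bool)
    st_dir = np.sign(stats_df["diff_ST_AC"].to_numpy(float)).astype(int)
    lt_dir = np.sign(stats_df["diff_LT_AC"].to_numpy(float)).astype(int)

    labels = np.full(n, TemplateLabel.NOT_SIGNIFICANT.value, dtype=object)
    labels[untestable] = TemplateLabel.UNTESTABLE.value
    labels[anova_sig & ~aging_sig] = TemplateLabel.NOT_AGING.value

    aging = anova_sig & aging_sig
    any_arm = st_sig | lt_sig
    same = (st_sig & (st_dir == aging_dir)) | (lt_sig & (lt_dir == aging_dir))
    labels[aging & ~any_arm & (aging_dir < 0)] = TemplateLabel.I.value
    labels[aging & ~any_arm & (aging_dir > 0)] = TemplateLabel.III.value
    labels[aging & any_arm & same] = TemplateLabel.ANOMALOUS.value
    countered = aging & any_arm & ~same
    labels[countered & (aging_dir < 0)] = TemplateLabel.II.value
    labels[countered & (aging_dir > 0)] = TemplateLabel.IV.value

    return pd.DataFrame({
        "gene_id": stats_df["gene_id"].to_numpy(),
        "label": labels,
        "aging_direction": np.where(aging, aging_dir, 0),
        "ST_direction": np.where(st_sig, st_dir, 0),
        "ST_significant": st_sig,
        "LT_direction": np.where(lt_sig, lt_dir, 0),
        "LT_significant": lt_sig,
    })


# ---------------------------------------------------------------------------
# Screen-level summaries
# ---------------------------------------------------------------------------

def summarize_classification(class_df: pd.DataFrame) -> ClassificationSummary:
    """Label counts and ST/LT arm bookkeeping over a classification table."""
    counts = {lab.value: int((class_df["label"] == lab.value).sum()) for lab in TemplateLabel}
    tested = class_df["label"] != TemplateLabel.UNTESTABLE.value
    sensitive = class_df["label"].isin([l.value for l in SENSITIVE_LABELS])
    st = class_df["ST_significant"].astype(bool) & sensitive
    lt = class_df["LT_significant"].astype(bool) & sensitive
    n_both = int((st & lt).sum())
    n_countered = counts["II"] + counts["IV"]
    n_unchanged = counts["I"] + counts["III"]
    return ClassificationSummary(
        counts=counts,
        n_tested=int(tested.sum()),
        n_aging_dependent=n_countered + n_unchanged + counts["ANOMALOUS"],
        n_sensitive=int(sensitive.sum()),
        n_countered=n_countered,
        n_unchanged=n_unchanged,
        n_st_only=int((st & ~lt).sum()),
        n_lt_only=int((lt & ~st).sum()),
        n_both=n_both,
    )


def concordance_stats(sensitive_means: pd.DataFrame) -> ConcordanceSummary:
    """ST/LT direction concordance and fold-change correlation.

    ``sensitive_means`` must carry columns ``mean_AC``, ``mean_ST``,
    ``mean_LT`` (positive, unlogged group means) for the rescue-sensitive
    genes.  A gene whose arm difference vs AC is exactly zero cannot be
    given a direction and is excluded from the concordance count (tallied
    in ``n_zero_diff_excluded``).  The binomial test is the exact one-sided
    upper tail against chance probability 0.5; the correlation is Pearson's
    r between the arms' log2 fold changes vs AC.
    """
    if len(sensitive_means) == 0:
        raise ValueError("need at least one sensitive gene")
    ac = sensitive_means["mean_AC"].to_numpy(float)
    st = sensitive_means["mean_ST"].to_numpy(float)
    lt = sensitive_means["mean_LT"].to_numpy(float)
    if np.nanmin(np.concatenate([ac, st, lt])) <= 0:
        raise ValueError("group means must be positive (unlogged scale)")
    d_st, d_lt = np.sign(st - ac), np.sign(lt - ac)
    usable = (d_st != 0) & (d_lt != 0)
    n_compared = int(usable.sum())
    n_same = int((d_st[usable] == d_lt[usable]).sum())
    frac = n_same / n_compared if n_compared else float("nan")
    binom_p = (
        stats.binomtest(n_same, n_compared, 0.5, alternative="greater").pvalue
        if n_compared else float("nan")
    )
    fc_st, fc_lt = np.log2(st / ac), np.log2(lt / ac)
    if len(fc_st) >= 2 and fc_st.min() < fc_st.max() and fc_lt.min() < fc_lt.max():
        r = float(stats.pearsonr(fc_lt, fc_st).statistic)
    else:
        r = float("nan")  # correlation undefined for a constant arm
    return ConcordanceSummary(
        n_sensitive=len(sensitive_means),
        n_compared=n_compared,
        n_same_direction=n_same,
        n_zero_diff_excluded=int(len(sensitive_means) - n_compared),
        concordance_fraction=frac,
        binomial_p_direction=float(binom_p),
        pearson_r=r,
    )


def overlap_enrichment(
    n_st_total: int, n_lt_total: int, n_both: int, n_universe: int
) -> OverlapResult:
    """Chance expectation for the ST/LT list overlap and its binomial tail.

    Under independent mechanisms a gene lands in both lists with probability
    (n_ST/N) * (n_LT/N); expected overlap is n_ST * n_LT / N.  The p-value
    is the exact one-sided upper binomial tail of observing >= n_both
    successes in N trials at that rate.
    """
    if n_universe <= 0:
        raise ValueError("n_universe must be positive")
    if not n_both <= min(n_st_total, n_lt_total) <= n_universe:
        raise ValueError("need n_both <= min(n_ST, n_LT) <= n_universe")
    p0 = (n_st_total / n_universe) * (n_lt_total / n_universe)
    expected = n_st_total * n_lt_total / n_universe
    fold = n_both / expected if expected > 0 else float("inf")
    p = stats.binomtest(n_both, n_universe, p0, alternative="greater").pvalue
    return OverlapResult(
        n_st_total=n_st_total, n_lt_total=n_lt_total, n_both=n_both,
        n_universe=n_universe, expected_both=expected, fold=fold,
        binomial_p=float(p),
    )
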