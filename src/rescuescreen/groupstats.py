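"""Per-gene four-group statistics.

For each gene the screen (i) masks within-group outliers, (ii) runs an
unbalanced one-way fixed-effects ANOVA across the four treatment groups,
(iii) evaluates Fisher's protected LSD pairwise contrasts against the
pooled residual mean square, and (iv) summarizes the screen with the
expected/observed false-discovery ratio.

Outlier masking is a single pass: the group mean and sample SD are computed
with every point included and any value more than ``outlier_sd`` SDs from
the mean becomes missing.  Note that for a group of n points the largest
attainable |x - mean| / SD is (n-1)/sqrt(n) (≈2.04 at n = 6), so the 2-SD
rule only ever removes a single, extreme point.

Protection means a pairwise contrast is only called significant when the
omnibus ANOVA is itself significant at the same alpha; the contrast t uses
the ANOVA's pooled MSE and residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_GROUPS, ExpressionStudy

#: Contrasts consumed by the template classifier, as (first, second) pairs;
#: the reported difference and direction are first minus second.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("YC", "AC"),
    ("LT", "AC"),
    ("ST", "AC"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for the per-gene screen.

    alpha
        Significance level shared by the ANOVA, the protected contrasts and
        downstream binomial tests (default 0.05).
    outlier_sd
        SD multiplier for single-pass within-group outlier masking
        (default 2).
    min_group_n
        Minimum retained values per group for a gene to stay testable
        (default 2).
    contrasts
        Ordered (first, second) group pairs; defaults to the three used by
        template classification.
    """

    alpha: float = 0.05
    outlier_sd: float = 2.0
    min_group_n: int = 2
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if self.min_group_n < 2:
            raise ValueError("min_group_n must be >= 2")


@dataclass
class MaskReport:
    n_masked: dict[str, int]
    untestable: bool = False

    @property
    def total_masked(self) -> int:
        return sum(self.n_masked.values())


@dataclass
class AnovaResult:
    f: float
    p: float
    mse: float
    df_between: int
    df_within: int
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    degenerate: bool = False


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    difference: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False


@dataclass
class GeneTestResult:
    gene_id: str
    anova: AnovaResult
    contrasts: list[ContrastResult] = field(default_factory=list)
    n_masked: int = 0
    untestable: bool = False


@dataclass
class ScreenSummary:
    n_tested: int
    n_anova_significant: int
    alpha: float

    @property
    def fdr(self) -> float:
        return estimate_fdr(self.n_tested, self.n_anova_significant, self.alpha)


# ---------------------------------------------------------------------------
# Scalar operations (one gene)
# ---------------------------------------------------------------------------

def mask_outliers(
    values_by_group: Mapping[str, Sequence[float]],
    outlier_sd: float = 2.0,
) -> tuple[dict[str, np.ndarray], MaskReport]:
    """Mask values more than ``outlier_sd`` group SDs from the group mean.

    One pass per group: mean and sample (n-1) SD include every non-missing
    point, candidates are masked simultaneously, and the rule is not
    re-applied to the masked data.  Groups with fewer than two non-missing
    values (or zero SD) are left untouched.
    """
    masked: dict[str, np.ndarray] = {}
    n_masked: dict[str, int] = {}
    untestable = False
    for group, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float).copy()
        ok = ~np.isnan(arr)
        if ok.sum() == 0:
            untestable = True
        if ok.sum() >= 2:
            mean = arr[ok].mean()
            sd = arr[ok].std(ddof=1)
            if sd > 0:
                out = ok & (np.abs(arr - mean) > outlier_sd * sd)
                arr[out] = np.nan
                n_masked[group] = int(out.sum())
        n_masked.setdefault(group, 0)
        masked[group] = arr
    return masked, MaskReport(n_masked=n_masked, untestable=untestable)


def anova_one_way(
    values_by_group: Mapping[str, Sequence[float]],
    min_group_n: int = 2,
) -> AnovaResult:
    """Unbalanced one-way fixed-effects ANOVA over the non-missing values.

    Groups retaining fewer than ``min_group_n`` values are excluded; fewer
    than two usable groups raises ``ValueError`` (the gene is untestable).
    Zero within-group variance with unequal means yields the degenerate
    F = inf, p = 0 flagged result.
    """
    groups: dict[str, np.ndarray] = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size >= min_group_n:
            groups[g] = arr
    if len(groups) < 2:
        raise ValueError("fewer than 2 groups with enough values: untestable")

    ns = {g: int(a.size) for g, a in groups.items()}
    means = {g: float(a.mean()) for g, a in groups.items()}
    n_total = sum(ns.values())
    k = len(groups)
    grand = sum(ns[g] * means[g] for g in groups) / n_total
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(float(((a - means[g]) ** 2).sum()) for g, a in groups.items())
    df_between = k - 1
    df_within = n_total - k
    mse = ss_within / df_within
    degenerate = False
    if ss_within == 0.0:
        if ss_between > 0.0:
            f, p, degenerate = np.inf, 0.0, True
        else:
            f, p = 0.0, 1.0
    else:
        f = (ss_between / df_between) / mse
        p = float(stats.f.sf(f, df_between, df_within))
    sems = {
        g: float(a.std(ddof=1) / np.sqrt(ns[g])) if ns[g] > 1 else np.nan
        for g, a in groups.items()
    }
    return AnovaResult(
        f=float(f), p=float(p), mse=float(mse),
        df_between=df_between, df_within=df_within,
        means=means, sems=sems, ns=ns, degenerate=degenerate,
    )


def plsd_contrasts(
    anova: AnovaResult,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[ContrastResult]:
    """Fisher's protected LSD pairwise contrasts from a fitted ANOVA.

    t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)), two-sided p on the
    ANOVA residual df; ``significant`` additionally requires the omnibus
    ANOVA p <= alpha (the protection).
    """
    out: list[ContrastResult] = []
    for pair in config.contrasts:
        i, j = pair
        if i not in anova.means or j not in anova.means:
            out.append(ContrastResult(pair, np.nan, np.nan, np.nan, False, True))
            continue
        diff = anova.means[i] - anova.means[j]
        if anova.mse == 0.0:
            t = np.inf * np.sign(diff) if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
            degenerate = True
        else:
            se = np.sqrt(anova.mse * (1.0 / anova.ns[i] + 1.0 / anova.ns[j]))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), anova.df_within))
            degenerate = False
        significant = bool(p <= config.alpha and anova.p <= config.alpha)
        out.append(ContrastResult(pair, float(diff), float(t), float(p), significant, degenerate))
    return out


def test_gene(
    gene_id: str,
    values_by_group: Mapping[str, Sequence[float]],
    config: AnalysisConfig = AnalysisConfig(),
    apply_masking: bool = True,
) -> GeneTestResult:
    """Full per-gene test: masking -> ANOVA -> protected contrasts."""
    if apply_masking:
        masked, report = mask_outliers(values_by_group, config.outlier_sd)
    else:
        masked = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
        report = MaskReport(n_masked={g: 0 for g in masked})
    usable = {
        g: a for g, a in masked.items()
        if (~np.isnan(a)).sum() >= config.min_group_n
    }
    if len(usable) < len(values_by_group):
        # the four-group screen needs every group; partial ANOVAs are
        # reported untestable rather than silently reinterpreted
        return GeneTestResult(
            gene_id=gene_id,
            anova=AnovaResult(np.nan, np.nan, np.nan, 0, 0, {}, {}, {}),
            n_masked=report.total_masked,
            untestable=True,
        )
    anova = anova_one_way(masked, config.min_group_n)
    contrasts = plsd_contrasts(anova, config)
    return GeneTestResult(
        gene_id=gene_id, anova=anova, contrasts=contrasts,
        n_masked=report.total_masked, untestable=False,
    )


def estimate_fdr(n_tested: int, n_significant: int, alpha: float) -> float:
    """Expected/observed false-discovery ratio: (alpha * n_tested) / n_significant.

    Returns ``nan`` (not-applicable) when nothing is significant.
    """
    if not 0 <= n_significant <= n_tested:
        raise ValueError("need 0 <= n_significant <= n_tested")
    if n_significant == 0:
        return float("nan")
    return alpha * n_tested / n_significant


# ---------------------------------------------------------------------------
# Vectorized screen (all genes at once)
# ---------------------------------------------------------------------------

def _mask_outliers_array(
    values: np.ndarray,
    group_cols: Mapping[str, np.ndarray],
    outlier_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized single-pass masking; returns (masked copy, per-gene mask count)."""
    masked = values.astype(float, copy=True)
    n_masked = np.zeros(values.shape[0], dtype=int)
    for cols in group_cols.values():
        block = masked[:, cols]
        n = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(block, axis=1)
            sd = np.nanstd(block, axis=1, ddof=1)
        applicable = (n >= 2) & (sd > 0)
        thresh = np.where(applicable, outlier_sd * sd, np.inf)
        out = np.abs(block - mean[:, None]) > thresh[:, None]
        out &= ~np.isnan(block)
        n_masked += out.sum(axis=1)
        block[out] = np.nan
        masked[:, cols] = block
    return masked, n_masked


def screen_arrays(
    values: np.ndarray,
    group_cols: Mapping[str, np.ndarray],
    config: AnalysisConfig = AnalysisConfig(),
    apply_masking: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized masking + ANOVA + protected LSD over a genes x samples array.

    ``group_cols`` maps group label -> column indices.  Returns a dict of
    per-gene arrays (keys: ``f``, ``p``, ``mse``, ``df_within``,
    ``untestable``, ``degenerate``, ``n_masked``, ``mean_<G>``, ``sem_<G>``,
    ``n_<G>`` per group, and ``diff/t/p/sig_<A>_<B>`` per contrast).
    Agrees with the scalar path to machine precision.
    """
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    labels = list(group_cols)
    k = len(labels)

    if apply_masking:
        masked, n_masked = _mask_outliers_array(values, group_cols, config.outlier_sd)
    else:
        masked, n_masked = values, np.zeros(n_genes, dtype=int)

    means = np.empty((n_genes, k))
    sems = np.empty((n_genes, k))
    ns = np.empty((n_genes, k), dtype=int)
    ssw = np.zeros(n_genes)
    for gi, g in enumerate(labels):
        block = masked[:, group_cols[g]]
        n = (~np.isnan(block)).sum(axis=1)
        ns[:, gi] = n
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(np.where(n[:, None] > 0, block, np.nan), axis=1)
            sd = np.nanstd(block, axis=1, ddof=1)
        means[:, gi] = m
        sems[:, gi] = sd / np.sqrt(np.maximum(n, 1))
        ssw += np.nansum((block - m[:, None]) ** 2, axis=1)

    untestable = (ns < config.min_group_n).any(axis=1)
    n_total = ns.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (ns * means).sum(axis=1) / n_total
        ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    df_between = k - 1
    df_within = n_total - k
    with np.errstate(invalid="ignore", divide="ignore"):
        mse = ssw / df_within
        f = (ssb / df_between) / mse
    degenerate = (ssw == 0) & (ssb > 0) & ~untestable
    all_flat = (ssw == 0) & (ssb == 0)
    f = np.where(degenerate, np.inf, f)
    f = np.where(all_flat, 0.0, f)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f, df_between, df_within)
    p = np.where(all_flat, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    f = np.where(untestable, np.nan, f)
    p = np.where(untestable, np.nan, p)

    out: dict[str, np.ndarray] = {
        "f": f, "p": p, "mse": mse,
        "df_within": df_within.astype(float),
        "untestable": untestable, "degenerate": degenerate,
        "n_masked": n_masked,
    }
    for gi, g in enumerate(labels):
        out[f"mean_{g}"] = means[:, gi]
        out[f"sem_{g}"] = sems[:, gi]
        out[f"n_{g}"] = ns[:, gi]

    gidx = {g: i for i, g in enumerate(labels)}
    anova_sig = ~untestable & (p <= config.alpha)
    for a, b in config.contrasts:
        ia, ib = gidx[a], gidx[b]
        diff = means[:, ia] - means[:, ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(mse * (1.0 / ns[:, ia] + 1.0 / ns[:, ib]))
            t = diff / se
        pc = np.full(n_genes, np.nan)
        ok = ~untestable & (mse > 0)
        pc[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_within[ok])
        zero_mse = ~untestable & (mse == 0)
        pc[zero_mse] = np.where(diff[zero_mse] != 0, 0.0, 1.0)
        t[zero_mse] = np.where(diff[zero_mse] != 0, np.inf * np.sign(diff[zero_mse]), 0.0)
        sig = anova_sig & (pc <= config.alpha)
        key = f"{a}_{b}"
        out[f"diff_{key}"] = diff
        out[f"t_{key}"] = t
        out[f"p_{key}"] = pc
        out[f"sig_{key}"] = sig
    return out


def screen_study(
    study: ExpressionStudy,
    config: AnalysisConfig = AnalysisConfig(),
    apply_masking: bool = True,
) -> pd.DataFrame:
    """Run the vectorized per-gene screen over a study.

    Returns one row per gene with group means/SEMs/ns after masking, the
    ANOVA F/p/MSE/df, and the protected contrasts.
    """
    study.require_all_groups()
    cols = {g: np.array([study.samples.get_loc(s) for s in ss])
            for g, ss in study.group_columns().items()}
    res = screen_arrays(study.values.to_numpy(dtype=float), cols, config, apply_masking)
    df = pd.DataFrame(res, index=study.gene_ids)
    df.insert(0, "gene_id", study.gene_ids)
    return df.reset_index(drop=True)


def summarize_screen(stats_df: pd.DataFrame, alpha: float) -> ScreenSummary:
    tested = ~stats_df["untestable"]
    n_sig = int((stats_df.loc[tested, "p"] <= alpha).sum())
    return ScreenSummary(n_tested=int(tested.sum()), n_anova_significant=n_sig, alpha=alpha)
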