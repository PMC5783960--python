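"""Monte Carlo chance expectation for template counts.

Each iteration replaces every gene's intensities with freshly drawn
independent standard-normal values (4 groups x n per group), runs the exact
screening procedure used on real data — one-way ANOVA, protected LSD
contrasts, template assignment — and tallies how many "genes" land in each
template.  The mean count across iterations estimates the number of genes
expected in a template by pure chance; observed counts are then expressed
as fold over that expectation with an exact one-sided binomial tail.

The null draws are i.i.d. within and across groups, so any distribution
would do (the group labels are exchangeable); standard normals are used
and documented.  Outlier masking is omitted by default, mirroring the
procedure's listed steps, and with 6 points per group the 2-SD rule is
essentially inert anyway (see :mod:`rescuescreen.groupstats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import AnalysisConfig, screen_arrays
from .templates import TemplateLabel, classify

#: Labels tallied per iteration.
TALLIED: tuple[str, ...] = (
    TemplateLabel.I.value, TemplateLabel.II.value, TemplateLabel.III.value,
    TemplateLabel.IV.value, TemplateLabel.ANOMALOUS.value,
    TemplateLabel.NOT_AGING.value, TemplateLabel.NOT_SIGNIFICANT.value,
)

#: Aggregates the screen reports alongside single templates.
AGGREGATES: dict[str, tuple[str, ...]] = {
    "II+IV": ("II", "IV"),
    "I+III": ("I", "III"),
    "I+II+III+IV+ANOMALOUS": ("I", "II", "III", "IV", "ANOMALOUS"),
}


@dataclass
class NullExpectation:
    """Per-template chance expectations from the random-data simulation."""

    n_genes: int
    n_per_group: int
    iterations: int
    seed: int
    expected: dict[str, float]            # mean count per label/aggregate
    sd: dict[str, float]                  # SD of the count across iterations
    counts: pd.DataFrame = field(repr=False)  # iterations x labels tally

    def expected_fraction(self, label: str) -> float:
        return self.expected[label] / self.n_genes


def run_null_simulation(
    n_genes: int,
    n_per_group: int = 6,
    iterations: int = 1000,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    apply_masking: bool = False,
) -> NullExpectation:
    """Estimate chance template counts from random data.

    Each of ``iterations`` draws an independent ``n_genes x (4 *
    n_per_group)`` standard-normal matrix and pushes it through the same
    vectorized ANOVA -> protected LSD -> template code path as real data.
    Deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n_genes < 1 or n_per_group < 2:
        raise ValueError("need n_genes >= 1 and n_per_group >= 2")
    rng = np.random.default_rng(seed)
    labels = ("YC", "AC", "ST", "LT")
    cols = {
        g: np.arange(i * n_per_group, (i + 1) * n_per_group)
        for i, g in enumerate(labels)
    }
    tallies = np.zeros((iterations, len(TALLIED)), dtype=int)
    gene_ids = np.arange(n_genes)
    for it in range(iterations):
        values = rng.standard_normal((n_genes, 4 * n_per_group))
        res = screen_arrays(values, cols, config, apply_masking=apply_masking)
        res["gene_id"] = gene_ids
        class_df = classify(pd.DataFrame(res), config)
        vc = class_df["label"].value_counts()
        tallies[it] = [int(vc.get(lab, 0)) for lab in TALLIED]
    counts = pd.DataFrame(tallies, columns=list(TALLIED))
    for agg, parts in AGGREGATES.items():
        counts[agg] = counts[list(parts)].sum(axis=1)
    expected = {c: float(counts[c].mean()) for c in counts.columns}
    sd = {c: float(counts[c].std(ddof=1)) if iterations > 1 else float("nan")
          for c in counts.columns}
    return NullExpectation(
        n_genes=n_genes, n_per_group=n_per_group, iterations=iterations,
        seed=seed, expected=expected, sd=sd, counts=counts,
    )


def fold_over_chance(
    observed: dict[str, int],
    expectation: NullExpectation,
) -> pd.DataFrame:
    """Observed/expected folds with exact binomial tails.

    ``observed`` maps template labels (and/or the aggregate keys ``II+IV``,
    ``I+III``) to observed gene counts from the real screen, which must come
    from the same number of genes as the simulation.  The binomial tail is
    P(X >= observed) with n = n_genes and chance rate expected/n_genes;
    when the simulation saw zero events the rate is floored at
    1 / (n_genes * iterations), the resolution of the simulation, and the
    fold is reported as infinite.
    """
    n = expectation.n_genes
    rows = []
    for label, obs in observed.items():
        if label not in expectation.expected:
            raise KeyError(f"no null expectation for {label!r}")
        exp = expectation.expected[label]
        if exp > 0:
            fold = obs / exp
            p0 = min(exp / n, 1.0)
        else:
            fold = float("inf") if obs > 0 else 0.0
            p0 = 1.0 / (n * expectation.iterations)
        p = stats.binomtest(int(obs), n, p0, alternative="greater").pvalue
        rows.append({
            "label": label, "observed": int(obs), "expected": exp,
            "expected_sd": expectation.sd[label], "fold": fold,
            "binomial_p": float(p),
        })
    return pd.DataFrame(rows)
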