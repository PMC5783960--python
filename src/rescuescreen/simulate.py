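"""Synthetic four-group expression studies with planted template classes.

The generator emulates the structure of the real screen: four treatment
groups (YC, AC, ST, LT) of six arrays each, ~15k genes with unlogged
RMA-scale intensities spanning roughly 40-9,000, multiplicative
within-group noise (SD = cv x group mean, matching the observed pattern of
SEMs roughly proportional to means), and planted effects:

* NULL genes share one mean across all four groups.
* Aging genes shift the AC mean by +/- ``aging_effect_size`` within-group
  SDs relative to YC; rescued arms return toward YC by
  ``restore_coefficient`` (1 = full restoration), non-rescued arms stay at
  the AC mean.  Rescue arms are drawn per the ``rescue_split`` over
  {ST-only, LT-only, both, none}; genes with no rescued arm are the
  planted templates I/III, genes with at least one are II/IV.
* A small exacerbated class shifts its rescue arms a further half effect
  size beyond AC in the aging direction (planted ANOMALOUS).

Baseline (YC) means are log-normal; the defaults put a realistic 5-10% of
genes below the intensity-40 presence threshold so the prefilter is
exercised.  Truth labels record the *planted* class of every gene, so
recovery of the classification can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import DEFAULT_GROUPS, ExpressionStudy, GeneSetCollection

TRUE_CLASSES = ("NULL", "I", "II", "III", "IV", "ANOMALOUS")

#: Planted effect unit relative to baseline in the noise-free (cv = 0) limit.
NOISE_FREE_EFFECT_FRACTION = 0.1

_TOL = 1e-9


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a planted four-group study.

    Defaults mirror the real screen: 14,828 genes, 6 arrays per group,
    ~15% of genes aging-dependent (split evenly up/down), rescue arms
    distributed as observed (LT-only most common, then ST-only, then
    both), full restoration, aging effects of 3 within-group SDs, CV 8%,
    and a log-normal intensity baseline spanning ~10-9,000.
    """

    n_genes: int = 14828
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 6
    fraction_null: float = 0.848
    fraction_aging_up: float = 0.075
    fraction_aging_down: float = 0.075
    fraction_exacerbated: float = 0.002
    rescue_split: Mapping[str, float] = field(
        default_factory=lambda: {"ST": 0.08, "LT": 0.22, "both": 0.07, "none": 0.63}
    )
    restore_coefficient: float = 1.0
    aging_effect_size: float = 3.0
    baseline_log_mean: float = 5.3
    baseline_log_sd: float = 1.1
    cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_null, self.fraction_aging_up,
            self.fraction_aging_down, self.fraction_exacerbated,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > _TOL:
            raise ValueError("class fractions must sum to 1")
        split = dict(self.rescue_split)
        if set(split) != {"ST", "LT", "both", "none"}:
            raise ValueError("rescue_split keys must be {ST, LT, both, none}")
        if any(not 0 <= v <= 1 for v in split.values()):
            raise ValueError("rescue_split proportions must lie in [0, 1]")
        if abs(sum(split.values()) - 1.0) > _TOL:
            raise ValueError("rescue_split must sum to 1")
        if not 0 <= self.restore_coefficient <= 1:
            raise ValueError("restore_coefficient must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if tuple(self.groups) != DEFAULT_GROUPS:
            raise ValueError(f"groups must be {DEFAULT_GROUPS}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.aging_effect_size * self.cv >= 1:
            raise ValueError(
                "aging_effect_size * cv must be < 1 so shifted means stay positive"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationDesign":
        d = dict(d)
        if "rescue_split" in d:
            d["rescue_split"] = dict(d["rescue_split"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth (classes refer to planted means)."""

    table: pd.DataFrame  # gene_id, true_class, true_aging_direction, true_rescue_arms

    def __post_init__(self) -> None:
        t = self.table
        bad = set(t["true_class"]) - set(TRUE_CLASSES)
        if bad:
            raise ValueError(f"unknown truth classes: {sorted(bad)}")
        has_arm = t["true_rescue_arms"] != ""
        rescue = t["true_class"].isin(["II", "IV", "ANOMALOUS"])
        if (rescue & ~has_arm).any() or (t["true_class"].isin(["I", "III"]) & has_arm).any():
            raise ValueError("rescue arms inconsistent with planted classes")

    def genes_of_class(self, cls: str) -> pd.Index:
        return pd.Index(self.table.loc[self.table["true_class"] == cls, "gene_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        t["true_aging_direction"] = t["true_aging_direction"].astype(int)
        return cls(t)


def _partition_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n items over fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)], kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_study(design: SimulationDesign) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Generate a planted study and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(design.seed)
    G, n = design.n_genes, design.n_per_group

    n_null, n_up, n_down, n_ex = _partition_counts(
        G,
        [design.fraction_null, design.fraction_aging_up,
         design.fraction_aging_down, design.fraction_exacerbated],
    )
    directions = np.zeros(G, dtype=int)
    classes = np.array(["NULL"] * G, dtype=object)
    order = rng.permutation(G)
    up_idx = order[n_null:n_null + n_up]
    down_idx = order[n_null + n_up:n_null + n_up + n_down]
    ex_idx = order[n_null + n_up + n_down:]
    directions[up_idx] = 1
    directions[down_idx] = -1
    # exacerbated genes alternate direction deterministically within the draw
    ex_dirs = np.where(np.arange(n_ex) % 2 == 0, 1, -1)
    directions[ex_idx] = ex_dirs

    # rescue arms for aging genes per the split; exacerbated genes always
    # have at least one arm (split renormalized without "none")
    arm_options = np.array(["ST", "LT", "ST,LT", ""], dtype=object)
    split = design.rescue_split
    probs = np.array([split["ST"], split["LT"], split["both"], split["none"]])
    arms = np.array([""] * G, dtype=object)
    aging_idx = np.concatenate([up_idx, down_idx])
    if len(aging_idx):
        arms[aging_idx] = rng.choice(arm_options, size=len(aging_idx), p=probs)
    if n_ex:
        p_arm = probs[:3]
        p_arm = p_arm / p_arm.sum() if p_arm.sum() > 0 else np.array([1 / 3] * 3)
        arms[ex_idx] = rng.choice(arm_options[:3], size=n_ex, p=p_arm)

    for idx in (up_idx, down_idx):
        rescued = arms[idx] != ""
        classes[idx] = np.where(
            directions[idx] > 0,
            np.where(rescued, "IV", "III"),
            np.where(rescued, "II", "I"),
        )
    classes[ex_idx] = "ANOMALOUS"

    # group means from the planted model; effects are measured in units of
    # the within-group SD (cv * mean), falling back to 10% of baseline in
    # the noise-free cv = 0 limit so planted structure stays visible
    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, size=G)
    sd_within = design.cv * baseline
    effect_unit = sd_within if design.cv > 0 else NOISE_FREE_EFFECT_FRACTION * baseline
    mean_yc = baseline
    mean_ac = baseline.copy()
    shifted = classes != "NULL"
    mean_ac[shifted] = baseline[shifted] + directions[shifted] * design.aging_effect_size * effect_unit[shifted]
    mean_st = mean_ac.copy()
    mean_lt = mean_ac.copy()
    has_st = np.isin(arms, ["ST", "ST,LT"])
    has_lt = np.isin(arms, ["LT", "ST,LT"])
    restored = mean_yc + (1.0 - design.restore_coefficient) * (mean_ac - mean_yc)
    normal_rescue = (classes != "ANOMALOUS") & shifted
    mean_st[normal_rescue & has_st] = restored[normal_rescue & has_st]
    mean_lt[normal_rescue & has_lt] = restored[normal_rescue & has_lt]
    exacerbated = classes == "ANOMALOUS"
    worse = mean_ac + directions * (design.aging_effect_size / 2.0) * effect_unit
    mean_st[exacerbated & has_st] = worse[exacerbated & has_st]
    mean_lt[exacerbated & has_lt] = worse[exacerbated & has_lt]

    group_means = {"YC": mean_yc, "AC": mean_ac, "ST": mean_st, "LT": mean_lt}
    values = np.empty((G, 4 * n))
    for gi, g in enumerate(design.groups):
        m = group_means[g]
        noise = rng.standard_normal((G, n))
        block = m[:, None] + (design.cv * m)[:, None] * noise
        values[:, gi * n:(gi + 1) * n] = block
    # unlogged intensities are strictly positive; extreme noise draws are
    # floored at a tiny epsilon (practically unreachable at default cv)
    np.maximum(values, 1e-6, out=values)

    width = len(str(G))
    gene_ids = pd.Index([f"G{i:0{width}d}" for i in range(G)], name="gene_id")
    samples = [f"{g}_{j + 1}" for g in design.groups for j in range(n)]
    group_of = pd.Series(
        [g for g in design.groups for _ in range(n)], index=samples, name="group"
    )
    annotations = pd.Series([f"gene{i}" for i in range(G)], index=gene_ids, name="annotation")
    study = ExpressionStudy(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        group_of=group_of,
        annotations=annotations,
        group_labels=design.groups,
    )
    truth = SyntheticTruth(pd.DataFrame({
        "gene_id": gene_ids,
        "true_class": classes,
        "true_aging_direction": directions,
        "true_rescue_arms": arms,
    }).reset_index(drop=True))
    return study, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_categories: int,
    enriched_class: str = "II",
    enrichment_factor: float = 1.0,
    seed: int = 0,
    n_enriched: int = 1,
    category_size: int = 40,
) -> GeneSetCollection:
    """Generate a GMT-writable collection with planted class enrichment.

    The first ``n_enriched`` categories sample genes with weights
    ``enrichment_factor`` for members of ``enriched_class`` and 1
    otherwise (``inf`` restricts sampling to the class); the remaining
    categories sample uniformly.  ``enrichment_factor=1`` makes every
    category independent of class membership.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if n_categories < 0 or n_enriched < 0:
        raise ValueError("counts must be non-negative")
    if n_categories == 0:
        return GeneSetCollection()
    n_enriched = min(n_enriched, n_categories)
    genes = truth.table["gene_id"].to_numpy()
    is_class = (truth.table["true_class"] == enriched_class).to_numpy()
    if not is_class.any():
        raise ValueError(f"class {enriched_class!r} absent from truth")
    if category_size > len(genes):
        raise ValueError("category_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    width = len(str(max(n_categories - 1, 1)))
    for ci in range(n_categories):
        if ci < n_enriched and enrichment_factor != 1.0:
            if np.isinf(enrichment_factor):
                pool = genes[is_class]
                size = min(category_size, len(pool))
                members = rng.choice(pool, size=size, replace=False)
            else:
                w = np.where(is_class, enrichment_factor, 1.0)
                members = rng.choice(
                    genes, size=category_size, replace=False, p=w / w.sum()
                )
            desc = f"planted enrichment of class {enriched_class}"
        else:
            members = rng.choice(genes, size=category_size, replace=False)
            desc = "random category"
        name = f"CAT{ci:0{width}d}"
        categories[name] = frozenset(members.tolist())
        descriptions[name] = desc
    return GeneSetCollection(categories=categories, descriptions=descriptions)
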