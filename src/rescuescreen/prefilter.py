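"""Presence/annotation prefilter on the probe universe.

A gene is "present" when its unlogged intensity reaches ``min_intensity``
on at least ``min_arrays`` arrays anywhere in the study (group-agnostic;
missing values count as below threshold).  When annotation is required,
unannotated genes are dropped and duplicate annotations are collapsed to
the probe with the highest mean intensity, so the retained universe has
unique gene annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy


@dataclass(frozen=True)
class FilterConfig:
    min_intensity: float = 40.0
    min_arrays: int = 4
    require_annotation: bool = True

    def __post_init__(self) -> None:
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")
        if self.min_arrays < 1:
            raise ValueError("min_arrays must be >= 1")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_failed_intensity: int
    n_unannotated: int
    n_duplicate_collapsed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(vars(self)), "count": list(vars(self).values())}
        )


def filter_present(
    study: ExpressionStudy, config: FilterConfig = FilterConfig()
) -> tuple[ExpressionStudy, FilterReport]:
    """Apply the presence + annotation filter; returns (filtered study, report).

    Raises ``ValueError`` when annotation is required but the study carries
    none, and when no gene survives (advising a threshold review).
    """
    vals = study.values.to_numpy(dtype=float)
    present = np.nan_to_num(vals, nan=-np.inf) >= config.min_intensity
    n_present_arrays = present.sum(axis=1)
    keep_intensity = n_present_arrays >= config.min_arrays
    n_failed_intensity = int((~keep_intensity).sum())

    keep = keep_intensity.copy()
    n_unannotated = 0
    n_dup = 0
    if config.require_annotation:
        if study.annotations is None:
            raise ValueError(
                "require_annotation=True but the study has no annotations; "
                "provide an annotation column or disable the requirement"
            )
        ann = study.annotations.fillna("").astype(str).str.strip()
        annotated = (ann != "").to_numpy()
        n_unannotated = int((keep & ~annotated).sum())
        keep &= annotated
        # collapse duplicate annotations to the probe with highest mean signal
        mean_signal = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=1)
        cand = pd.DataFrame({
            "gene": study.gene_ids[keep],
            "symbol": ann.to_numpy()[keep],
            "mean": mean_signal[keep],
        })
        winners = (
            cand.sort_values(["symbol", "mean", "gene"], kind="mergesort")
            .groupby("symbol", sort=False)
            .tail(1)["gene"]
        )
        n_dup = int(keep.sum()) - len(winners)
        keep = study.gene_ids.isin(winners)

    retained_ids = study.gene_ids[keep]
    if len(retained_ids) == 0:
        raise ValueError(
            "no genes retained by the presence filter; review min_intensity/"
            "min_arrays against the data scale"
        )
    report = FilterReport(
        n_input=study.n_genes,
        n_retained=int(keep.sum()),
        n_failed_intensity=n_failed_intensity,
        n_unannotated=n_unannotated,
        n_duplicate_collapsed=n_dup,
    )
    return study.subset(retained_ids), report
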