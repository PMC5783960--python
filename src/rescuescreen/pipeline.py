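"""End-to-end screen orchestration and report bookkeeping.

``run_screen`` chains prefilter -> per-gene statistics -> template
classification -> concordance/overlap summaries -> Monte Carlo null ->
per-template enrichment, writing deterministic TSV tables plus one
machine-readable JSON summary.  Printed percentages follow a fixed
rounding convention (half away from zero) so headline ratios such as
876/2342 -> "37%" and 822/876 -> "93.8%" are reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich_list
from .groupstats import AnalysisConfig, estimate_fdr, screen_study, summarize_screen
from .io import ExpressionStudy, read_expression_matrix, read_gmt, write_results
from .nullmc import fold_over_chance, run_null_simulation
from .prefilter import FilterConfig, filter_present
from .templates import (
    SENSITIVE_LABELS,
    TEMPLATES,
    classify,
    concordance_stats,
    overlap_enrichment,
    summarize_classification,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def format_percent(numerator: float, denominator: float, decimals: int = 0) -> str:
    """Render a ratio as a percentage, rounding half away from zero.

    ``format_percent(876, 2342)`` -> ``"37%"``;
    ``format_percent(822, 876, 1)`` -> ``"93.8%"``.
    """
    if denominator == 0:
        return "NA"
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    matrix_path: str
    samples_path: str
    out_dir: str
    gmt_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    null_iterations: int = 1000
    run_null: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        filt = FilterConfig(**d.pop("filter", {}))
        ana = d.pop("analysis", {})
        if "contrasts" in ana:
            ana["contrasts"] = tuple(tuple(p) for p in ana["contrasts"])
        return cls(filter=filt, analysis=AnalysisConfig(**ana), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def run_screen(config: RunConfig, study: ExpressionStudy | None = None) -> dict[str, Any]:
    """Run the full screen; returns the JSON-serializable summary dict.

    ``study`` may be passed directly (e.g. a generated one) instead of
    reading ``matrix_path``/``samples_path``.  All outputs land in
    ``config.out_dir``; reruns with the same inputs and seed are
    byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = config.analysis.alpha

    if study is None:
        study = _stage("read")(
            read_expression_matrix, config.matrix_path, config.samples_path
        )

    filtered, filter_report = _stage("filter")(filter_present, study, config.filter)
    write_results(filter_report.as_frame(), out_dir / "filter_report.tsv")

    stats_df = _stage("test")(screen_study, filtered, config.analysis)
    write_results(stats_df, out_dir / "gene_stats.tsv", sort_by="gene_id")
    screen = summarize_screen(stats_df, alpha)

    class_df = _stage("classify")(classify, stats_df, config.analysis)
    write_results(class_df, out_dir / "templates.tsv", sort_by="gene_id")
    summary = summarize_classification(class_df)

    # concordance + overlap over the rescue-sensitive genes
    sens_mask = class_df["label"].isin([l.value for l in SENSITIVE_LABELS])
    conc = None
    overlap = None
    if sens_mask.any():
        sens = stats_df.loc[sens_mask.to_numpy(), ["mean_AC", "mean_ST", "mean_LT"]]
        conc = _stage("concordance")(concordance_stats, sens)
        overlap = _stage("overlap")(
            overlap_enrichment,
            summary.n_st_total, summary.n_lt_total, summary.n_both,
            summary.n_aging_dependent,
        )
        conc_df = pd.DataFrame([vars(conc)])
        write_results(conc_df, out_dir / "concordance.tsv")
    else:
        write_results(pd.DataFrame(), out_dir / "concordance.tsv")

    null_tbl = None
    if config.run_null:
        expectation = _stage("null")(
            run_null_simulation,
            n_genes=screen.n_tested,
            n_per_group=min(
                int(stats_df[f"n_{g}"].max()) for g in ("YC", "AC", "ST", "LT")
            ),
            iterations=config.null_iterations,
            config=config.analysis,
            seed=config.seed,
        )
        observed = {t.value: summary.counts[t.value] for t in TEMPLATES}
        observed["ANOMALOUS"] = summary.counts["ANOMALOUS"]
        observed["II+IV"] = summary.n_countered
        observed["I+III"] = summary.n_unchanged
        null_tbl = _stage("null")(fold_over_chance, observed, expectation)
        write_results(null_tbl, out_dir / "null_report.tsv")

    enrichment_files: dict[str, str] = {}
    if config.gmt_path:
        collection = _stage("enrich")(read_gmt, config.gmt_path)
        background = filtered.gene_ids.tolist()
        for t in TEMPLATES:
            genes = class_df.loc[class_df["label"] == t.value, "gene_id"].tolist()
            tbl = _stage("enrich")(enrich_list, genes, collection, background, alpha)
            path = out_dir / f"enrichment_{t.value}.tsv"
            write_results(tbl, path)
            enrichment_files[t.value] = path.name  # relative, keeps reruns byte-identical

    n_ad = summary.n_aging_dependent
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "alpha": alpha,
            "outlier_sd": config.analysis.outlier_sd,
            "min_group_n": config.analysis.min_group_n,
            "min_intensity": config.filter.min_intensity,
            "min_arrays": config.filter.min_arrays,
            "require_annotation": config.filter.require_annotation,
            "null_iterations": config.null_iterations if config.run_null else 0,
        },
        "filter": vars(filter_report),
        "screen": {
            "n_tested": screen.n_tested,
            "n_anova_significant": screen.n_anova_significant,
            "fdr": estimate_fdr(screen.n_tested, screen.n_anova_significant, alpha)
            if screen.n_anova_significant else None,
            "pct_anova_significant": format_percent(
                screen.n_anova_significant, screen.n_tested
            ),
        },
        "classification": {
            "counts": summary.counts,
            "n_aging_dependent": n_ad,
            "n_sensitive": summary.n_sensitive,
            "n_countered": summary.n_countered,
            "n_unchanged": summary.n_unchanged,
            "n_st_only": summary.n_st_only,
            "n_lt_only": summary.n_lt_only,
            "n_both": summary.n_both,
            "pct_aging_dependent": format_percent(n_ad, screen.n_anova_significant)
            if screen.n_anova_significant else "NA",
            "pct_sensitive": format_percent(summary.n_sensitive, n_ad)
            if n_ad else "NA",
            "pct_countered_of_sensitive": format_percent(
                summary.n_countered, summary.n_sensitive, 1
            ) if summary.n_sensitive else "NA",
        },
        "concordance": vars(conc) if conc else None,
        "overlap": vars(overlap) if overlap else None,
        "null": null_tbl.to_dict(orient="records") if null_tbl is not None else None,
        "enrichment_files": enrichment_files,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    summary_rows = pd.DataFrame(
        [{"key": k, "value": v} for k, v in _flatten(report).items()]
    )
    write_results(summary_rows, out_dir / "summary.tsv")
    return report


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            flat.update(_flatten(v, key + "."))
        elif isinstance(v, list):
            flat[key] = json.dumps(v)
        else:
            flat[key] = v
    return flat
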