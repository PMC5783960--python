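"""EASE-score gene-set overrepresentation against the filtered background.

The Fisher p-value for a category is the hypergeometric upper tail
P(X >= h) of drawing ``h`` category genes in a list of size ``L`` from a
background of ``B`` genes containing ``K`` category members.  The EASE
score is the conservative ("jackknifed") variant used by DAVID: the same
tail evaluated after removing one gene from the list-category overlap,
P(X >= max(h - 1, 0)), so a category supported by a single gene can never
score.  Categories are retained when they carry more than three list genes
and the EASE score reaches the significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: A category must have more list genes than this to be retained.
MIN_HITS_EXCLUSIVE = 3


@dataclass
class EnrichmentRecord:
    category: str
    description: str
    n_hits: int
    list_size: int
    category_size_in_background: int
    background_size: int
    ease_p: float
    fisher_p: float
    retained: bool


def _upper_tail(h: int, background: int, category: int, draws: int) -> float:
    """P(X >= h) for X ~ Hypergeom(background, category, draws)."""
    if h <= 0:
        return 1.0
    return float(stats.hypergeom.sf(h - 1, background, category, draws))


def ease_score(
    n_hits: int, list_size: int, category_size: int, background_size: int
) -> tuple[float, float]:
    """Return ``(ease_p, fisher_p)`` for one category.

    ``fisher_p`` is the plain one-tailed hypergeometric upper tail;
    ``ease_p`` replaces ``n_hits`` with ``max(n_hits - 1, 0)`` in the same
    tail, hence ``ease_p >= fisher_p`` always.
    """
    if not 0 <= n_hits <= min(list_size, category_size):
        raise ValueError("need 0 <= n_hits <= min(list_size, category_size)")
    if background_size < max(list_size, category_size):
        raise ValueError("background must contain the list and the category")
    fisher_p = _upper_tail(n_hits, background_size, category_size, list_size)
    ease_p = _upper_tail(max(n_hits - 1, 0), background_size, category_size, list_size)
    return ease_p, fisher_p


def enrich_list(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every category against a gene list, ranked by EASE score.

    Category membership is counted within the background only; genes
    outside the background are excluded from categories with a logged
    count.  ``retained`` requires more than three list genes in the
    category and EASE p <= alpha.  A Benjamini-Hochberg column over the
    raw Fisher p-values is included for information only.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    lst = set(gene_list)
    if not lst <= bg:
        raise ValueError("gene list must be a subset of the background")
    rows = []
    n_outside = 0
    for name, members in collection.categories.items():
        in_bg = members & bg
        n_outside += len(members) - len(in_bg)
        if not in_bg:
            continue
        h = len(in_bg & lst)
        ease_p, fisher_p = ease_score(h, len(lst), len(in_bg), len(bg))
        rows.append({
            "category": name,
            "description": collection.descriptions.get(name, ""),
            "n_hits": h,
            "list_size": len(lst),
            "category_size_in_background": len(in_bg),
            "background_size": len(bg),
            "ease_p": ease_p,
            "fisher_p": fisher_p,
            "retained": bool(h > MIN_HITS_EXCLUSIVE and ease_p <= alpha),
        })
    if n_outside:
        logger.info("%d category gene(s) outside the background excluded", n_outside)
    columns = [
        "category", "description", "n_hits", "list_size",
        "category_size_in_background", "background_size",
        "ease_p", "fisher_p", "fisher_p_bh", "retained",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["fisher_p_bh"] = stats.false_discovery_control(df["fisher_p"], method="bh")
    df = df.sort_values(["ease_p", "category"], kind="mergesort").reset_index(drop=True)
    return df[columns]
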