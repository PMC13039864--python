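"""Transcription-factor overlay on trajectory category gene lists.

Each category's gene list is intersected with a curated registry of human
TF symbols (e.g. the Lambert catalogue) after the same symbol normalization
used for expression data; the report carries per-category TF membership and
percentages.  Registry symbols never seen in any category are reported
rather than silently dropped — symbol-vocabulary drift between catalogues
is the main failure mode of this step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import TFRegistry, normalize_symbol

__all__ = ["TFCategoryReport", "annotate_tfs"]


@dataclass(frozen=True)
class TFCategoryReport:
    """Per-category TF counts and membership.

    ``summary`` has one row per category with columns n_genes, n_tf,
    tf_percent; ``tf_genes`` maps each category to its sorted TF list;
    ``unmatched_registry`` holds registry symbols absent from every
    category's gene list.
    """

    summary: pd.DataFrame
    tf_genes: Mapping[str, list[str]]
    unmatched_registry: list[str]


def annotate_tfs(
    category_genes: Mapping[str, Iterable[str]], registry: TFRegistry
) -> TFCategoryReport:
    """Overlay the TF registry onto category gene lists.

    tf_percent is 100 * n_tf / n_genes, defined as 0 for an empty category.
    """
    rows = []
    tf_genes: dict[str, list[str]] = {}
    seen: set[str] = set()
    for category, genes in category_genes.items():
        members = {normalize_symbol(g) for g in genes}
        seen |= members
        tfs = sorted(members & registry.symbols)
        tf_genes[category] = tfs
        n_genes = len(members)
        n_tf = len(tfs)
        rows.append(
            {
                "category": category,
                "n_genes": n_genes,
                "n_tf": n_tf,
                "tf_percent": 100.0 * n_tf / n_genes if n_genes else 0.0,
            }
        )
    summary = pd.DataFrame(rows, columns=["category", "n_genes", "n_tf", "tf_percent"])
    unmatched = sorted(registry.symbols - seen)
    return TFCategoryReport(summary, tf_genes, unmatched)
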