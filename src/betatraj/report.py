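"""Figure-ready reporting: heatmap row ordering, the three-hairpin knockdown
intersection filter, and the 2^-ddCt qPCR utility.

Heatmap ordering follows two rules.  Single-stage and down-regulated
category heatmaps sort genes by their average FPKM across the D20 and D35
samples of all models.  The three up-both category heatmaps sort by the
difference between the average FPKM at D35 and at D20 — largest increase
first for increasing categories, largest decrease first for decreasing
ones.

The knockdown filter keeps, per shRNA condition, genes with adjusted
p < 0.05 and |log2 fold change| > 0.5, and intersects the up and down lists
across all conditions.  An "absolute FC" threshold of 0.5 is not
interpretable on the linear scale (every upregulated gene would trivially
pass), so the filter works on |log2 FC|: with the default
``fc_scale="linear"`` the positive linear fold_change column is log2'd
internally; ``fc_scale="log2"`` declares that the column already holds
signed log2 fold changes (pass a plain DataFrame in that case, since the
linear-scale DE-table contract requires positive values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DETable, ExpressionMatrix, SampleSheet

__all__ = [
    "HeatmapOrder",
    "KnockdownFilterConfig",
    "order_heatmap",
    "knockdown_intersect",
    "ddct",
]

SortRule = Literal["MEAN_FPKM", "DELTA_D35_D20"]


@dataclass(frozen=True)
class HeatmapOrder:
    """Deterministic row order for one category's heatmap."""

    category: str
    rule: str
    ordered_genes: list[str]
    sort_key: pd.Series
    top_n: list[str]


def order_heatmap(
    category: str,
    genes: Iterable[str],
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    rule: SortRule = "MEAN_FPKM",
    top_n: int | None = None,
    timepoints: Sequence[str] = ("D20", "D35"),
    largest_decrease_first: bool = False,
) -> HeatmapOrder:
    """Order a category's genes for heatmap display.

    MEAN_FPKM sorts descending by the mean FPKM over the ``timepoints``
    samples of all models.  DELTA_D35_D20 sorts by mean(D35) - mean(D20),
    descending (largest increase first), or by the most negative difference
    first when ``largest_decrease_first`` is set (for decreasing
    categories).  Ties break lexicographically by symbol.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")

    def stage_samples(tp: str) -> list[str]:
        return [
            s
            for model in sheet.models
            for s in sheet.samples_for(model, tp)
        ]

    sub = matrix.data.loc[genes]
    if rule == "MEAN_FPKM":
        samples = [s for tp in timepoints for s in stage_samples(tp)]
        key = sub[samples].mean(axis=1)
        ascending = False
    elif rule == "DELTA_D35_D20":
        d35 = sub[stage_samples("D35")].mean(axis=1)
        d20 = sub[stage_samples("D20")].mean(axis=1)
        key = d35 - d20
        ascending = largest_decrease_first
    else:
        raise ValueError(f"unknown heatmap sort rule {rule!r}")

    order = (
        pd.DataFrame({"key": key, "gene": key.index})
        .sort_values(["key", "gene"], ascending=[ascending, True], kind="mergesort")
        .index.tolist()
    )
    top = order if top_n is None else order[: max(top_n, 0)]
    return HeatmapOrder(category, rule, order, key, top)


@dataclass(frozen=True)
class KnockdownFilterConfig:
    """Thresholds for the per-condition knockdown DE filter."""

    p_adj_max: float = 0.05
    abs_log2fc_min: float = 0.5
    fc_scale: Literal["linear", "log2"] = "linear"

    def __post_init__(self) -> None:
        if self.p_adj_max <= 0 or self.abs_log2fc_min <= 0:
            raise ValueError("thresholds must be positive")


def knockdown_intersect(
    tables: Mapping[str, DETable | pd.DataFrame],
    config: KnockdownFilterConfig = KnockdownFilterConfig(),
) -> tuple[list[str], list[str]]:
    """Genes commonly down- and upregulated across all knockdown conditions.

    Per condition: down = {p_adjusted < p_adj_max and log2FC < -abs_log2fc_min},
    up = {p_adjusted < p_adj_max and log2FC > +abs_log2fc_min}; inequalities
    are strict.  Returns the sorted intersections across all conditions.
    """
    if not tables:
        raise ValueError("no knockdown DE tables supplied")
    common_down: set[str] | None = None
    common_up: set[str] | None = None
    for condition, table in tables.items():
        df = table.data if isinstance(table, DETable) else table
        if "p_adjusted" not in df.columns:
            raise ValueError(f"condition {condition!r} DE table lacks p_adjusted")
        fc = df["fold_change"].to_numpy(dtype=float)
        log2fc = np.log2(fc) if config.fc_scale == "linear" else fc
        sig = df["p_adjusted"].to_numpy(dtype=float) < config.p_adj_max
        down = set(df.loc[sig & (log2fc < -config.abs_log2fc_min), "gene_id"])
        up = set(df.loc[sig & (log2fc > config.abs_log2fc_min), "gene_id"])
        common_down = down if common_down is None else common_down & down
        common_up = up if common_up is None else common_up & up
    return sorted(common_down), sorted(common_up)


def ddct(
    ct: pd.DataFrame,
    control_condition: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` needs columns sample, condition, target_ct, reference_ct.  Per
    sample, dCt = target Ct - reference Ct; ddCt subtracts the mean dCt of
    the control condition; relative expression is 2^-ddCt, so the control
    condition's mean-centred sample has expression 1 and one extra cycle
    (ddCt = 1) halves it.
    """
    required = {"sample", "condition", "target_ct", "reference_ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct[["target_ct", "reference_ct"]].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    if control_condition not in set(ct["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from Ct table")
    out = ct.copy()
    out["dct"] = out["target_ct"].astype(float) - out["reference_ct"].astype(float)
    control_mean = out.loc[out["condition"] == control_condition, "dct"].mean()
    out["ddct"] = out["dct"] - control_mean
    out["relative_expression"] = np.exp2(-out["ddct"])
    return out
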