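"""Trajectory stratification: eight-category classification of time-course DE.

Each gene is compared against the baseline day (D0) at two later stages —
endocrine progenitors (D20) and beta-like cells (D35).  A gene is called UP
at a stage when its fold change exceeds ``fc_up`` (default 2.0) with
p < ``p_max`` (default 0.05), DOWN when the fold change is below ``fc_down``
(default 0.5) with p < ``p_max``, and NS otherwise.  Genes up at both stages
are split by the change-in-FC ratio r = FC(D35) / FC(D20): increasing when
r > 1.5, decreasing when r < 0.5, near-constant when 0.5 <= r <= 1.5.  For
example, FC 2 at D20 and FC 6 at D35 give r = 6/2 = 3: increasing.

This yields eight trajectory categories per model (cell line background,
e.g. hESC vs hiPSC), plus two bookkeeping labels: DISCORDANT for genes UP at
one stage and DOWN at the other, and UNCLASSIFIED for everything else.
Categories are then intersected across models so that only genes assigned
the same category in every model survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .de import ComparisonResult
from .io import DETable

__all__ = [
    "Thresholds",
    "Status",
    "RatioBin",
    "CATEGORIES",
    "ALL_LABELS",
    "StratificationResult",
    "call_status",
    "bin_ratio",
    "classify_gene",
    "stratify_model",
    "category_sets",
    "intersect_models",
    "stratify",
]

Status = Literal["UP", "DOWN", "NS"]
RatioBin = Literal["INCREASING", "DECREASING", "NEAR_CONSTANT"]

#: The eight trajectory categories, in canonical reporting order.
CATEGORIES: tuple[str, ...] = (
    "UP_D20_ONLY",
    "UP_D35_ONLY",
    "UP_BOTH_NEAR_CONSTANT",
    "UP_BOTH_INCREASING",
    "UP_BOTH_DECREASING",
    "DOWN_BOTH",
    "DOWN_D20_ONLY",
    "DOWN_D35_ONLY",
)

#: Categories plus the two bookkeeping labels.
ALL_LABELS: tuple[str, ...] = CATEGORIES + ("DISCORDANT", "UNCLASSIFIED")


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs for differential calls and change-in-FC binning.

    ``strict_fc`` controls whether the fold-change cut-offs are strict
    (``FC > 2.0``, the literal reading) or inclusive (``FC >= 2.0``).
    """

    fc_up: float = 2.0
    fc_down: float = 0.5
    p_max: float = 0.05
    ratio_up: float = 1.5
    ratio_down: float = 0.5
    strict_fc: bool = True

    def __post_init__(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError("need fc_down < 1 < fc_up")
        if not (self.ratio_down < 1.0 < self.ratio_up):
            raise ValueError("need ratio_down < 1 < ratio_up")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("need 0 < p_max <= 1")


def call_status(fc: float, p: float, thresholds: Thresholds = Thresholds()) -> Status:
    """Differential status of one gene at one stage: UP, DOWN or NS."""
    if thresholds.strict_fc:
        up = fc > thresholds.fc_up
        down = fc < thresholds.fc_down
    else:
        up = fc >= thresholds.fc_up
        down = fc <= thresholds.fc_down
    if p < thresholds.p_max:
        if up:
            return "UP"
        if down:
            return "DOWN"
    return "NS"


def bin_ratio(r: float, thresholds: Thresholds = Thresholds()) -> RatioBin:
    """Bin a change-in-FC ratio r = FC(D35)/FC(D20).

    r > 1.5 is increasing, r < 0.5 decreasing, and the closed interval
    [0.5, 1.5] (boundaries included) near-constant.
    """
    if not (r > 0):
        raise ValueError(f"change-in-FC ratio must be positive, got {r}")
    if r > thresholds.ratio_up:
        return "INCREASING"
    if r < thresholds.ratio_down:
        return "DECREASING"
    return "NEAR_CONSTANT"


def classify_gene(
    status_d20: Status,
    status_d35: Status,
    r: float,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Map a (D20, D35) status pair plus change-in-FC ratio to a category."""
    pair = (status_d20, status_d35)
    if pair == ("UP", "NS"):
        return "UP_D20_ONLY"
    if pair == ("NS", "UP"):
        return "UP_D35_ONLY"
    if pair == ("UP", "UP"):
        return f"UP_BOTH_{bin_ratio(r, thresholds)}"
    if pair == ("DOWN", "DOWN"):
        return "DOWN_BOTH"
    if pair == ("DOWN", "NS"):
        return "DOWN_D20_ONLY"
    if pair == ("NS", "DOWN"):
        return "DOWN_D35_ONLY"
    if pair in (("UP", "DOWN"), ("DOWN", "UP")):
        return "DISCORDANT"
    return "UNCLASSIFIED"


def stratify_model(
    comparison_d20: ComparisonResult | DETable,
    comparison_d35: ComparisonResult | DETable,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene assignment for one model.

    Returns a frame indexed by gene with columns fc_d20, p_d20, fc_d35,
    p_d35, r, status_d20, status_d35, category.  The two DE tables must
    cover the same genes.
    """
    t20 = comparison_d20.table if isinstance(comparison_d20, ComparisonResult) else comparison_d20
    t35 = comparison_d35.table if isinstance(comparison_d35, ComparisonResult) else comparison_d35
    d20 = t20.data.set_index("gene_id")
    d35 = t35.data.set_index("gene_id")
    if set(d20.index) != set(d35.index):
        only = set(d20.index) ^ set(d35.index)
        raise ValueError(
            f"D20 and D35 DE tables cover different genes ({len(only)} mismatched)"
        )
    d35 = d35.loc[d20.index]

    out = pd.DataFrame(
        {
            "fc_d20": d20["fold_change"].to_numpy(dtype=float),
            "p_d20": d20["p_value"].to_numpy(dtype=float),
            "fc_d35": d35["fold_change"].to_numpy(dtype=float),
            "p_d35": d35["p_value"].to_numpy(dtype=float),
        },
        index=d20.index,
    )
    out["r"] = out["fc_d35"] / out["fc_d20"]
    out["status_d20"] = [
        call_status(fc, p, thresholds) for fc, p in zip(out["fc_d20"], out["p_d20"])
    ]
    out["status_d35"] = [
        call_status(fc, p, thresholds) for fc, p in zip(out["fc_d35"], out["p_d35"])
    ]
    out["category"] = [
        classify_gene(s20, s35, r, thresholds)
        for s20, s35, r in zip(out["status_d20"], out["status_d35"], out["r"])
    ]
    return out


def category_sets(
    assignment: pd.DataFrame, count_discordant_in_only: bool = False
) -> dict[str, set[str]]:
    """Gene sets per label from a per-model assignment frame.

    With ``count_discordant_in_only`` a discordant gene (UP one stage, DOWN
    the other) is additionally counted in the two matching single-stage
    categories; the gene algebra of the eight categories is otherwise silent
    about such genes.
    """
    sets: dict[str, set[str]] = {label: set() for label in ALL_LABELS}
    for gene, row in assignment.iterrows():
        sets[row["category"]].add(gene)
    if count_discordant_in_only:
        disc = assignment[assignment["category"] == "DISCORDANT"]
        for gene, row in disc.iterrows():
            if row["status_d20"] == "UP":  # (UP, DOWN)
                sets["UP_D20_ONLY"].add(gene)
                sets["DOWN_D35_ONLY"].add(gene)
            else:  # (DOWN, UP)
                sets["DOWN_D20_ONLY"].add(gene)
                sets["UP_D35_ONLY"].add(gene)
    return sets


def intersect_models(
    per_model_sets: Mapping[str, Mapping[str, Iterable[str]]],
) -> dict[str, list[str]]:
    """Per-category intersection of gene sets across >=2 models, sorted.

    A gene survives a category only if every model assigned it that same
    category (for up-both genes this means the same ratio bin in every
    model).
    """
    if len(per_model_sets) < 2:
        raise ValueError(
            "intersection requires >=2 models; use the per-model assignment instead"
        )
    intersected: dict[str, list[str]] = {}
    for label in ALL_LABELS:
        common: set[str] | None = None
        for model_sets in per_model_sets.values():
            genes = set(model_sets.get(label, ()))
            common = genes if common is None else (common & genes)
        intersected[label] = sorted(common or ())
    return intersected


@dataclass(frozen=True)
class StratificationResult:
    """Per-model assignments plus the cross-model category intersection."""

    per_model: Mapping[str, pd.DataFrame]
    intersected: Mapping[str, list[str]]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def category_counts(self) -> pd.DataFrame:
        rows = {}
        for model, assignment in self.per_model.items():
            counts = assignment["category"].value_counts()
            rows[model] = [int(counts.get(label, 0)) for label in ALL_LABELS]
        rows["intersected"] = [len(self.intersected[label]) for label in ALL_LABELS]
        return pd.DataFrame(rows, index=list(ALL_LABELS))


def stratify(
    comparisons: Sequence[ComparisonResult],
    thresholds: Thresholds = Thresholds(),
    count_discordant_in_only: bool = False,
    target_early: str = "D20",
    target_late: str = "D35",
) -> StratificationResult:
    """Full stratification from a list of per-model, per-stage contrasts.

    ``comparisons`` must contain, for every model, one contrast for the early
    target stage and one for the late target stage (both against the same
    baseline).
    """
    by_model: dict[str, dict[str, ComparisonResult]] = {}
    for comp in comparisons:
        by_model.setdefault(comp.model, {})[comp.target] = comp

    per_model: dict[str, pd.DataFrame] = {}
    per_model_sets: dict[str, dict[str, set[str]]] = {}
    for model in sorted(by_model):
        comps = by_model[model]
        for needed in (target_early, target_late):
            if needed not in comps:
                raise ValueError(f"model {model!r} lacks a {needed} contrast")
        assignment = stratify_model(comps[target_early], comps[target_late], thresholds)
        per_model[model] = assignment
        per_model_sets[model] = category_sets(assignment, count_discordant_in_only)

    if len(per_model) >= 2:
        intersected = intersect_models(per_model_sets)
    else:
        # single-model run: the "intersection" is that model's own sets
        only = next(iter(per_model_sets.values()))
        intersected = {label: sorted(only[label]) for label in ALL_LABELS}
    return StratificationResult(per_model, intersected, thresholds)
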