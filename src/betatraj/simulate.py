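"""Synthetic bulk RNA-seq with planted trajectory categories.

The generator emulates the study design downstream stages expect: two cell
models (hESC- and hiPSC-derived differentiations) sampled at a baseline day
and two later stages, three replicates each, FPKM-like abundances.  Every
gene is planted in one of the eight trajectory categories (or as
unclassified background): its mean abundance at stage t is
``baseline_mean * planted_fc(t)`` and replicate values multiply that mean by
log-normal noise ``2**eps`` with ``eps ~ Normal(0, noise_sd)``.

Planted fold changes sit at least a configurable safety factor beyond every
threshold they must clear, so the categories are recoverable under noise;
a config whose planted FCs violate their category's defining inequalities
is rejected before simulation.  A fraction of genes per category is flagged
as transcription factors, and per-category gene sets can be emitted as a
ground-truth oracle for the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleSheet,
    TFRegistry,
)
from .stratify import CATEGORIES, Thresholds, bin_ratio, call_status, classify_gene

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "DEFAULT_PLANTED_FC",
    "simulate",
    "plant_enriched_sets",
    "truth_registry",
    "write_truth",
    "read_truth",
]

#: Planted (FC at D20, FC at D35) per category.  Each value clears the
#: thresholds it must satisfy by at least the default 1.5x safety factor:
#: up calls use FC 3 or more (threshold 2), down calls use FC 0.25
#: (threshold 0.5), and the change-in-FC ratios are 3 (increasing,
#: threshold 1.5), 0.25 (decreasing, threshold 0.5) and 1 (near-constant).
DEFAULT_PLANTED_FC: dict[str, tuple[float, float]] = {
    "UP_D20_ONLY": (3.0, 1.0),
    "UP_D35_ONLY": (1.0, 3.0),
    "UP_BOTH_NEAR_CONSTANT": (3.0, 3.0),
    "UP_BOTH_INCREASING": (3.0, 9.0),
    "UP_BOTH_DECREASING": (12.0, 3.0),
    "DOWN_BOTH": (0.25, 0.25),
    "DOWN_D20_ONLY": (0.25, 1.0),
    "DOWN_D35_ONLY": (1.0, 0.25),
    "UNCLASSIFIED": (1.0, 1.0),
}

DEFAULT_N_GENES: dict[str, int] = {**{c: 50 for c in CATEGORIES}, "UNCLASSIFIED": 200}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    noise_sd is the standard deviation of the log2-scale replicate noise;
    0.25 corresponds to a typical replicate spread of roughly 1.2-fold.
    ``discordance_fraction`` reassigns that fraction of planted genes to a
    different category in every model after the first, to exercise loss at
    the cross-model intersection.
    """

    n_genes_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_GENES)
    )
    planted_fc: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_FC)
    )
    baseline_mean: float = 100.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    models: Sequence[str] = ("hESC", "hiPSC")
    timepoints: Sequence[str] = ("D0", "D20", "D35")
    tf_fraction: float = 0.1
    safety_factor: float = 1.5
    discordance_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not (0.0 <= self.tf_fraction <= 1.0):
            raise ValueError("tf_fraction must be in [0, 1]")
        if not (0.0 <= self.discordance_fraction <= 1.0):
            raise ValueError("discordance_fraction must be in [0, 1]")
        if len(self.models) < 1:
            raise ValueError("need at least one model")
        if len(self.timepoints) != 3:
            raise ValueError("expected a baseline plus two target timepoints")
        self.validate_planted_fc()

    def validate_planted_fc(self, thresholds: Thresholds = Thresholds()) -> None:
        """Reject planted FCs that violate their category with margin.

        UP calls must reach ``fc_up * safety_factor``, DOWN calls
        ``fc_down / safety_factor``, NS calls must stay inside
        ``[fc_down * safety_factor, fc_up / safety_factor]``; change-in-FC
        ratios analogously for the three up-both bins.
        """
        s = self.safety_factor
        for category, count in self.n_genes_per_category.items():
            if count < 0:
                raise ValueError(f"negative gene count for {category}")
            if count == 0 or category == "UNCLASSIFIED":
                continue
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
            if category not in self.planted_fc:
                raise ValueError(f"no planted FC for category {category!r}")
            fc20, fc35 = self.planted_fc[category]
            want20, want35 = _expected_statuses(category)
            for stage, fc, want in (("D20", fc20, want20), ("D35", fc35, want35)):
                if want == "UP" and fc < thresholds.fc_up * s:
                    raise ValueError(
                        f"{category}: planted {stage} FC {fc} below "
                        f"{thresholds.fc_up}*{s} safety margin for an UP call"
                    )
                if want == "DOWN" and fc > thresholds.fc_down / s:
                    raise ValueError(
                        f"{category}: planted {stage} FC {fc} above "
                        f"{thresholds.fc_down}/{s} safety margin for a DOWN call"
                    )
                if want == "NS" and not (
                    thresholds.fc_down * s <= fc <= thresholds.fc_up / s
                ):
                    raise ValueError(
                        f"{category}: planted {stage} FC {fc} outside the "
                        f"NS safety band [{thresholds.fc_down * s}, {thresholds.fc_up / s}]"
                    )
            if category.startswith("UP_BOTH"):
                r = fc35 / fc20
                bin_want = category.removeprefix("UP_BOTH_")
                if bin_want == "INCREASING" and r < thresholds.ratio_up * s:
                    raise ValueError(f"{category}: ratio {r} below increasing margin")
                if bin_want == "DECREASING" and r > thresholds.ratio_down / s:
                    raise ValueError(f"{category}: ratio {r} above decreasing margin")
                if bin_want == "NEAR_CONSTANT" and not (
                    thresholds.ratio_down * s <= r <= thresholds.ratio_up / s
                ):
                    raise ValueError(f"{category}: ratio {r} outside near-constant band")


def _expected_statuses(category: str) -> tuple[str, str]:
    """(D20 status, D35 status) a category's genes must exhibit."""
    return {
        "UP_D20_ONLY": ("UP", "NS"),
        "UP_D35_ONLY": ("NS", "UP"),
        "UP_BOTH_NEAR_CONSTANT": ("UP", "UP"),
        "UP_BOTH_INCREASING": ("UP", "UP"),
        "UP_BOTH_DECREASING": ("UP", "UP"),
        "DOWN_BOTH": ("DOWN", "DOWN"),
        "DOWN_D20_ONLY": ("DOWN", "NS"),
        "DOWN_D35_ONLY": ("NS", "DOWN"),
        "UNCLASSIFIED": ("NS", "NS"),
    }[category]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth record per simulated gene.

    ``data`` is indexed by gene_id with columns category, is_tf,
    planted_fc_d20, planted_fc_d35 (the first model's planted values; under
    model discordance, per-model FCs are in ``model_fc``).
    """

    data: pd.DataFrame
    model_fc: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    def category_genes(self, category: str) -> list[str]:
        return sorted(self.data.index[self.data["category"] == category])


def simulate(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, SampleSheet, PlantedTruth]:
    """Draw one synthetic experiment; identical config and seed reproduce it."""
    rng = np.random.default_rng(config.seed)

    genes: list[str] = []
    categories: list[str] = []
    order = [c for c in (*CATEGORIES, "UNCLASSIFIED") if c in config.n_genes_per_category]
    for category in order:
        for i in range(config.n_genes_per_category[category]):
            genes.append(f"SIM{len(genes):05d}")
            categories.append(category)
    n = len(genes)
    if n == 0:
        raise ValueError("config plants no genes")

    is_tf = rng.random(n) < config.tf_fraction
    base_fc = np.array([config.planted_fc[c] for c in categories])  # (n, 2)

    # per-model planted FCs; discordant genes swap to another category's FCs
    # in every model after the first
    model_fc: dict[str, pd.DataFrame] = {}
    per_model = {}
    for m, model in enumerate(config.models):
        fc = base_fc.copy()
        if m > 0 and config.discordance_fraction > 0:
            hit = rng.random(n) < config.discordance_fraction
            pool = list(config.planted_fc)
            for i in np.flatnonzero(hit):
                other = [c for c in pool if c != categories[i]]
                fc[i] = config.planted_fc[other[rng.integers(len(other))]]
        per_model[model] = fc
        model_fc[model] = pd.DataFrame(
            fc, index=pd.Index(genes, name="gene_id"), columns=["fc_d20", "fc_d35"]
        )

    baseline, early, late = config.timepoints
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for model in config.models:
        fc = per_model[model]
        stage_fc = {baseline: np.ones(n), early: fc[:, 0], late: fc[:, 1]}
        for timepoint in config.timepoints:
            means = config.baseline_mean * stage_fc[timepoint]
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{model}_{timepoint}_R{rep}"
                eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
                columns[sample_id] = means * np.exp2(eps)
                sheet_rows.append(
                    {"sample_id": sample_id, "model": model, "timepoint": timepoint, "replicate": rep}
                )

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=pd.Index(genes, name="gene_id")))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = PlantedTruth(
        pd.DataFrame(
            {
                "category": categories,
                "is_tf": is_tf,
                "planted_fc_d20": base_fc[:, 0],
                "planted_fc_d35": base_fc[:, 1],
            },
            index=pd.Index(genes, name="gene_id"),
        ),
        model_fc,
    )
    return matrix, sheet, truth


def plant_enriched_sets(
    truth: PlantedTruth,
    config: SimulationConfig = SimulationConfig(),
    member_fraction: float = 0.8,
    n_background_members: int = 10,
) -> GeneSetCollection:
    """One gene set per non-empty category: a fraction of the category's
    genes plus random background members, enriched by construction."""
    if not (0.0 < member_fraction <= 1.0):
        raise ValueError("member_fraction must be in (0, 1]")
    if len(truth.data) == 0:
        raise ValueError("empty truth table")
    rng = np.random.default_rng(config.seed + 1)
    all_genes = np.asarray(truth.data.index)
    sets: dict[str, GeneSet] = {}
    for category in CATEGORIES:
        members = truth.category_genes(category)
        if not members:
            continue
        k = max(1, int(round(member_fraction * len(members))))
        picked = set(rng.choice(members, size=k, replace=False))
        others = np.asarray([g for g in all_genes if g not in picked])
        if n_background_members > 0 and len(others):
            extra = rng.choice(others, size=min(n_background_members, len(others)), replace=False)
            picked |= set(extra)
        sets[f"{category}_SET"] = GeneSet(f"planted set for {category}", frozenset(picked))
    return GeneSetCollection(sets)


def truth_registry(truth: PlantedTruth, source_label: str = "planted") -> TFRegistry:
    """TF registry containing exactly the genes flagged is_tf."""
    symbols = frozenset(truth.data.index[truth.data["is_tf"]])
    if not symbols:
        raise ValueError("no genes flagged as transcription factors")
    return TFRegistry(symbols, source_label)


def write_truth(truth: PlantedTruth, path) -> None:
    truth.data.to_csv(path, sep="\t")


def read_truth(path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["is_tf"] = df["is_tf"].astype(bool)
    return PlantedTruth(df)
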