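"""Per-model, per-timepoint differential expression against a baseline day.

Fold change is the ratio of group means on the linear (FPKM) scale with a
small pseudocount, FC = (mean(target) + c) / (mean(baseline) + c); the
p-value is a Welch two-sample t-test on log2(x + 1)-transformed replicate
values.  Degenerate inputs follow fixed rules: fewer than two replicates in
either group gives p = 1; two zero-variance groups give p = 1 when their
means agree and p = 0 when they differ (perfect separation).

Externally computed DE tables can be passed straight through to the
stratifier, keeping it independent of any one DE engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DETable, ExpressionMatrix, SampleSheet

__all__ = [
    "ComparisonResult",
    "compute_fold_change",
    "compute_p_value",
    "run_contrasts",
]

DEFAULT_PSEUDOCOUNT = 0.01  # FPKM; avoids division by zero without distorting expressed genes


@dataclass(frozen=True)
class ComparisonResult:
    """One timepoint-vs-baseline contrast within one model."""

    model: str
    target: str
    baseline: str
    table: DETable

    @property
    def name(self) -> str:
        return f"{self.model}_{self.target}_vs_{self.baseline}"


def _as_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} replicate vector is empty")
    if (arr < 0).any():
        raise ValueError(f"{name} contains negative values")
    return arr


def compute_fold_change(
    baseline_values: Sequence[float],
    target_values: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Linear fold change of replicate means, FC = (mean(t)+c)/(mean(b)+c)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    base = _as_array(baseline_values, "baseline")
    targ = _as_array(target_values, "target")
    denom = base.mean() + pseudocount
    numer = targ.mean() + pseudocount
    if denom == 0.0:
        raise ZeroDivisionError(
            "fold change undefined: baseline mean and pseudocount are both zero"
        )
    return float(numer / denom)


def compute_p_value(
    baseline_values: Sequence[float], target_values: Sequence[float]
) -> float:
    """Welch two-sample p-value on log2(x + 1) replicate values."""
    base = np.log2(_as_array(baseline_values, "baseline") + 1.0)
    targ = np.log2(_as_array(target_values, "target") + 1.0)
    if base.size < 2 or targ.size < 2:
        return 1.0
    if base.var(ddof=1) == 0.0 and targ.var(ddof=1) == 0.0:
        return 1.0 if base.mean() == targ.mean() else 0.0
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(base, targ, equal_var=False).pvalue
    if np.isnan(p):
        return 1.0
    return float(min(max(p, 0.0), 1.0))


def run_contrasts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    baseline: str = "D0",
    targets: Sequence[str] = ("D20", "D35"),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[ComparisonResult]:
    """One ComparisonResult per (model, target timepoint), every gene present."""
    results: list[ComparisonResult] = []
    values = matrix.data
    for model in sheet.models:
        base_samples = sheet.samples_for(model, baseline)
        if not base_samples:
            raise ValueError(f"model {model!r} has no {baseline} baseline samples")
        base = values[base_samples].to_numpy(dtype=float)
        for target in targets:
            targ_samples = sheet.samples_for(model, target)
            if not targ_samples:
                raise ValueError(f"model {model!r} has no {target} samples")
            targ = values[targ_samples].to_numpy(dtype=float)
            fc = (targ.mean(axis=1) + pseudocount) / (base.mean(axis=1) + pseudocount)
            p = _welch_rows(np.log2(base + 1.0), np.log2(targ + 1.0))
            table = DETable(
                pd.DataFrame(
                    {
                        "gene_id": matrix.gene_ids,
                        "fold_change": fc,
                        "p_value": p,
                    }
                )
            )
            results.append(ComparisonResult(model, target, baseline, table))
    return results


def _welch_rows(base: np.ndarray, targ: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values with the degenerate rules applied."""
    n_genes = base.shape[0]
    if base.shape[1] < 2 or targ.shape[1] < 2:
        return np.ones(n_genes)
    var_b = base.var(axis=1, ddof=1)
    var_t = targ.var(axis=1, ddof=1)
    both_const = (var_b == 0.0) & (var_t == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's precision warning; they are overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(base, targ, axis=1, equal_var=False).pvalue
    mean_diff = base.mean(axis=1) != targ.mean(axis=1)
    p = np.where(both_const, np.where(mean_diff, 0.0, 1.0), p)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
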