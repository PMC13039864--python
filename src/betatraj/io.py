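"""Data model and text-format I/O for the stratification pipeline.

Everything downstream operates on a small set of symbol-keyed containers:
an FPKM-like expression matrix (genes x samples), a sample sheet assigning
each sample to a (model, timepoint, replicate) triple, per-contrast
differential-expression (DE) tables, a transcription-factor registry, and
GMT gene-set collections.  Gene identifiers are symbols, uppercased with
surrounding whitespace stripped, because the TF catalogue and the published
gene lists are symbol-keyed.

All formats are plain tab-separated text; writers and readers round-trip
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "DETable",
    "TFRegistry",
    "GeneSet",
    "GeneSetCollection",
    "FormatError",
    "normalize_symbol",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_de_table",
    "write_de_table",
    "read_tf_registry",
    "write_tf_registry",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file violated its expected text format."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and uppercased.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples abundance table (FPKM-like, non-negative).

    ``data`` is indexed by normalized gene symbol with one column per sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("expression values contain NaN")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sample with model, timepoint, replicate."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "model", "timepoint", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        triples = self.data[["model", "timepoint", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (model, timepoint, replicate) triple")
        if (self.data["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive")

    @property
    def models(self) -> list[str]:
        return sorted(self.data["model"].unique())

    @property
    def timepoints(self) -> list[str]:
        return list(pd.unique(self.data["timepoint"]))

    def samples_for(self, model: str, timepoint: str) -> list[str]:
        mask = (self.data["model"] == model) & (self.data["timepoint"] == timepoint)
        return list(self.data.loc[mask, "sample_id"])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


@dataclass(frozen=True)
class DETable:
    """Per-gene differential expression for one contrast.

    Columns: ``gene_id``, ``fold_change`` (linear scale, > 0), ``p_value``,
    optionally ``p_adjusted``.  One row per gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_id", "fold_change", "p_value"):
            if col not in self.data.columns:
                raise ValueError(f"DE table missing column {col!r}")
        if self.data["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in DE table")
        if (self.data["fold_change"] <= 0).any() or not np.isfinite(
            self.data["fold_change"]
        ).all():
            raise ValueError("fold_change must be finite and > 0")
        for col in ("p_value", "p_adjusted"):
            if col in self.data.columns:
                p = self.data[col].to_numpy(dtype=float)
                if ((p < 0) | (p > 1)).any():
                    raise ValueError(f"{col} outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DETable) and self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


@dataclass(frozen=True)
class TFRegistry:
    """Set of transcription-factor gene symbols, normalized like matrix genes."""

    symbols: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("TF registry is empty")
        object.__setattr__(
            self, "symbols", frozenset(normalize_symbol(s) for s in self.symbols)
        )

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class GeneSet:
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set has no members")
        object.__setattr__(
            self, "members", frozenset(normalize_symbol(s) for s in self.members)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. GO BP terms for enrichment."""

    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and dict(self.sets) == dict(
            other.sets
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DuplicateRule = Literal["error", "first", "max-mean"]


def read_expression_matrix(
    path: str | Path, duplicates: DuplicateRule = "max-mean"
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    First column holds gene symbols, the header row holds sample ids, and every
    remaining cell must be a non-negative number.  Symbols are normalized; rows
    sharing a normalized symbol are collapsed per ``duplicates``:

    - ``"max-mean"`` (default): keep the row with the largest mean abundance
    - ``"first"``: keep the first occurrence
    - ``"error"``: refuse the file
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        seen: set[str] = set()
        dupes = sorted({s for s in sample_ids if s in seen or seen.add(s)})
        raise FormatError(f"duplicate sample header(s) in {path.name}: {dupes}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path.name}"
        )
    numeric.index = [normalize_symbol(g) for g in numeric.index]
    numeric.index.name = raw.index.name or "gene_id"

    if numeric.index.has_duplicates:
        if duplicates == "error":
            dupes = sorted(numeric.index[numeric.index.duplicated()].unique())
            raise FormatError(f"duplicate gene symbols in {path.name}: {dupes[:5]}")
        if duplicates == "first":
            numeric = numeric[~numeric.index.duplicated(keep="first")]
        elif duplicates == "max-mean":
            means = numeric.mean(axis=1).to_numpy()
            pos: dict[str, int] = {}
            for p, (sym, m) in enumerate(zip(numeric.index, means)):
                if sym not in pos or m > means[pos[sym]]:
                    pos[sym] = p
            numeric = numeric.iloc[sorted(pos.values())]
        else:
            raise ValueError(f"unknown duplicate rule {duplicates!r}")
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "model": str, "timepoint": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> DETable:
    df = pd.read_csv(path, sep="\t")
    df["gene_id"] = [normalize_symbol(g) for g in df["gene_id"]]
    return DETable(df)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_tf_registry(path: str | Path, source_label: str | None = None) -> TFRegistry:
    """Read a one-symbol-per-line TF list; blank lines are ignored."""
    path = Path(path)
    symbols = {
        normalize_symbol(line)
        for line in path.read_text().splitlines()
        if line.strip()
    }
    if not symbols:
        raise FormatError(f"TF registry {path.name} contains no symbols")
    return TFRegistry(frozenset(symbols), source_label or path.name)


def write_tf_registry(registry: TFRegistry, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(registry.symbols)) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member [<TAB> member ...]."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        name, description, *members = fields
        members = [m for m in members if m.strip()]
        if not members:
            raise FormatError(f"{path.name}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
        sets[name] = GeneSet(description, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, gs in collection:
        lines.append("\t".join([name, gs.description, *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
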