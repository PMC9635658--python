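"""Core data containers: the gene-by-feature table and labeled gene sets.

The feature table is the sole model input for the whole pipeline.  It keeps
two congruent frames: ``values`` (floats, with missing cells already imputed
to 0 so that models can consume the matrix directly) and ``missing`` (a
boolean mask marking which cells were imputed).  Statistical summaries use
:attr:`FeatureTable.raw`, where imputed cells are NaN, so imputation never
leaks into medians, correlations or rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "LabeledGeneSet", "read_labels_tsv", "write_labels_tsv"]


@dataclass
class FeatureTable:
    """Gene x feature real-valued matrix with an explicit missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with feature names as columns.  Missing
        cells must already be imputed (default policy: 0).
    missing
        Boolean DataFrame congruent to ``values``; True marks imputed cells.
        If omitted, NaNs in ``values`` are taken as missing and imputed to 0.
    """

    values: pd.DataFrame
    missing: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = self.values.isna()
            self.values = self.values.fillna(0.0)
        self.values = self.values.astype(float)
        self.missing = self.missing.astype(bool)
        self.values.index.name = "gene_id"
        self.missing.index.name = "gene_id"
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dups[:5]}")
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape does not match values")
        if not (self.missing.index.equals(self.values.index)
                and self.missing.columns.equals(self.values.columns)):
            raise ValueError("missing mask index/columns do not match values")
        finite = np.isfinite(self.values.to_numpy())
        if not (finite | self.missing.to_numpy()).all():
            raise ValueError("non-missing values must be finite")

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def raw(self) -> pd.DataFrame:
        """Values with imputed cells restored to NaN (for statistics)."""
        return self.values.where(~self.missing)

    def matrix(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Model-ready float matrix, rows in the order of ``genes``."""
        if genes is None:
            return self.values.to_numpy(dtype=float)
        missing_ids = [g for g in genes if g not in self.values.index]
        if missing_ids:
            raise KeyError(f"unknown gene ids: {missing_ids[:10]}")
        return self.values.loc[list(genes)].to_numpy(dtype=float)

    def drop_features(self, names: Iterable[str]) -> "FeatureTable":
        names = list(names)
        unknown = [n for n in names if n not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        if len(names) >= len(self.feature_names):
            raise ValueError("removing these features would empty the table")
        return FeatureTable(
            self.values.drop(columns=names), self.missing.drop(columns=names)
        )

    def check_same_features(self, feature_names: Sequence[str]) -> None:
        """Raise unless this table's feature order matches exactly."""
        if list(feature_names) != self.feature_names:
            raise ValueError(
                "feature order mismatch: expected "
                f"{list(feature_names)[:5]}..., got {self.feature_names[:5]}..."
            )

    # -- TSV round trip --------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        """Read a feature table TSV (first column gene_id, missing as NA)."""
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        frame.index = frame.index.astype(str)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.raw.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class LabeledGeneSet:
    """Disjoint positive gene set and negative gene pool.

    Positives are the known causal genes used for training; the negative
    pool is every other gene from which per-model negative sets are drawn.
    """

    positives: frozenset[str]
    negative_pool: frozenset[str]

    def __init__(self, positives: Iterable[str], negative_pool: Iterable[str]):
        object.__setattr__(self, "positives", frozenset(positives))
        object.__setattr__(self, "negative_pool", frozenset(negative_pool))
        if not self.positives:
            raise ValueError("positive set must be non-empty")
        overlap = self.positives & self.negative_pool
        if overlap:
            raise ValueError(f"positives and negative pool overlap: {sorted(overlap)[:5]}")

    def check_in_table(self, table: FeatureTable) -> None:
        index = set(table.gene_ids)
        stray = (self.positives | self.negative_pool) - index
        if stray:
            raise ValueError(f"labeled genes absent from table: {sorted(stray)[:10]}")


def read_labels_tsv(path: str | Path) -> LabeledGeneSet:
    """Read a two-column TSV (gene_id, label in {positive, negative})."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "label"} <= set(frame.columns):
        raise ValueError("labels TSV needs columns gene_id and label")
    bad = set(frame["label"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    pos = frame.loc[frame["label"] == "positive", "gene_id"]
    neg = frame.loc[frame["label"] == "negative", "gene_id"]
    return LabeledGeneSet(pos, neg)


def write_labels_tsv(labels: LabeledGeneSet, path: str | Path) -> None:
    rows = [(g, "positive") for g in sorted(labels.positives)]
    rows += [(g, "negative") for g in sorted(labels.negative_pool)]
    pd.DataFrame(rows, columns=["gene_id", "label"]).to_csv(path, sep="\t", index=False)
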