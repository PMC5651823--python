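"""Annotated gene x sample expression container.

The whole pipeline passes a single container around: a gene x sample table of
abundances plus a per-sample metadata frame (tissue, condition H/A/T, source
cohort, subject) and a scale tag recording what the numbers mean (raw counts,
CPM, log2 CPM, or generic abundance).  This mirrors the DGEList-style objects
used by count-based DE frameworks, but stays a thin wrapper over two pandas
DataFrames so every stage can use ordinary pandas/numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Valid values of the ``scale`` tag.
SCALES = ("counts", "cpm", "log2cpm", "abundance")

#: Valid condition labels: healthy, tumor-adjacent (NAT), tumor.
CONDITIONS = ("H", "A", "T")

#: Columns every metadata frame must carry (``distance`` is optional).
META_COLUMNS = ("sample", "tissue", "condition", "source", "subject")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        DataFrame with one row per sample, columns
        ``sample, tissue, condition, source, subject`` (plus optional
        ``distance``); ``condition`` in {H, A, T}.  Row order matches the
        column order of ``values``.
    scale
        One of ``counts``, ``cpm``, ``log2cpm``, ``abundance``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "counts"
    #: free-form provenance notes (normalization factors etc.)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        missing = [c for c in META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        self.samples = self.samples.reset_index(drop=True)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if list(self.values.columns) != list(self.samples["sample"]):
            raise ValueError("values columns and metadata 'sample' column disagree (ids or order)")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if self.scale in ("counts", "cpm") and (arr < 0).any():
            # log-scale matrices (log2cpm, generic abundance) may dip below zero
            raise ValueError(f"negative abundances are not allowed on scale {self.scale!r}")
        if self.scale == "counts":
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("scale 'counts' requires integer entries")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` (kept in the given order)."""
        sub = self.values.loc[list(genes)]
        return replace(self, values=sub, samples=self.samples.copy())

    def subset_samples(self, mask) -> "ExpressionMatrix":
        """Return a copy restricted to samples selected by boolean ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        vals = self.values.loc[:, self.values.columns[mask]]
        meta = self.samples.loc[mask].reset_index(drop=True)
        return replace(self, values=vals, samples=meta)

    def select(self, tissue: str | None = None, condition: str | None = None) -> "ExpressionMatrix":
        mask = np.ones(self.n_samples, dtype=bool)
        if tissue is not None:
            mask &= (self.samples["tissue"] == tissue).to_numpy()
        if condition is not None:
            mask &= (self.samples["condition"] == condition).to_numpy()
        return self.subset_samples(mask)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, samples=self.samples.copy(),
                                scale=scale or self.scale, attrs=dict(self.attrs))

    def tissues(self) -> list[str]:
        return list(pd.unique(self.samples["tissue"]))
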