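"""Core tabular containers shared across the pipeline.

All tables are oriented features x samples.  Sample identifiers are
ISO-formatted collection dates (a time series has one sample per date), and
feature metadata (classification system, lineage) travels with the matrix so
that tables from different classification systems can be written, read and
joined without side files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoverageTable", "ProportionTable", "ZScoreTable"]


def _as_dates(columns) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(pd.to_datetime(list(columns)))


@dataclass
class CoverageTable:
    """Sample-by-feature matrix of summed read coverage.

    Parameters
    ----------
    data : DataFrame
        Features (rows) by samples (columns); non-negative coverage values.
    meta : DataFrame
        Indexed like ``data``; columns ``system`` (classification system,
        e.g. ``family``/``KO``/``Pfam``) and ``lineage`` (semicolon-delimited
        GTDB-style string, empty for functional features).
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"system": "", "lineage": ""}, index=self.data.index
            )
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same feature index")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def dates(self) -> pd.DatetimeIndex:
        """Sample collection dates parsed from the column labels."""
        return _as_dates(self.data.columns)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, system: str) -> "CoverageTable":
        """Restrict to features of one classification system."""
        mask = self.meta["system"] == system
        return CoverageTable(self.data.loc[mask], self.meta.loc[mask])


@dataclass
class ProportionTable:
    """Relative proportions per sample, with the rare-feature filter state.

    ``data`` holds proportions for *all* features (each column sums to one);
    ``retained`` flags the features that survive the mean-abundance filter and
    ``totals`` stores the per-sample coverage sums so the original coverage is
    recoverable.
    """

    data: pd.DataFrame
    retained: pd.Series
    totals: pd.Series
    threshold: float = 0.0
    meta: pd.DataFrame | None = None

    @property
    def dates(self) -> pd.DatetimeIndex:
        return _as_dates(self.data.columns)

    @property
    def retained_data(self) -> pd.DataFrame:
        return self.data.loc[self.retained]

    @property
    def dropped_features(self) -> list[str]:
        return list(self.data.index[~self.retained])


@dataclass
class ZScoreTable:
    """Per-feature standardized proportions (mean 0, sd 1 across samples)."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return _as_dates(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Samples x features array, the orientation ordinations consume."""
        return self.data.to_numpy().T
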