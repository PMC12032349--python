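"""Community average genome size (AGS) from single-copy marker genes.

In an assembled metagenome each of 139 universally single-copy marker gene
families occurs once per genome, so a marker family's coverage-weighted
count estimates the number of genome equivalents in the assembly.  The
average genome size is then

    AGS = N_bases_assembly / N_genomes

with N_genomes the central (mean) estimate across the markers.  Dispersion
across markers is the internal reliability check: when the coefficient of
variation (sd/mean) reaches 50% the estimate is flagged unreliable and no
AGS value is reported for that sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomaly import SeasonalAnomalyModel

__all__ = ["AGSEstimate", "estimate_ags", "ags_series"]

#: CV at or above this flags the estimate unreliable.
CV_LIMIT = 0.5


@dataclass
class AGSEstimate:
    n_bases_assembly: float
    marker_counts: pd.Series  # per-marker genome-count estimates
    n_genomes: float
    cv: float
    reliable: bool

    @property
    def ags(self) -> float | None:
        """Average genome size in base pairs; None when unreliable."""
        if not self.reliable:
            return None
        return self.n_bases_assembly / self.n_genomes


def estimate_ags(marker_counts, total_bases: float) -> AGSEstimate:
    """Estimate AGS for one sample.

    Parameters
    ----------
    marker_counts : array-like
        Coverage-weighted counts for the single-copy markers.  Markers
        absent from the assembly must be passed as zeros — they inflate the
        CV and naturally trip the reliability flag on shallow samples.
    total_bases : float
        Total assembled bases of the sample.
    """
    counts = pd.Series(marker_counts, dtype=float)
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if (counts < 0).any():
        raise ValueError("marker counts must be non-negative")
    if not (counts > 0).any():
        raise ValueError("all marker counts are zero")
    n_genomes = float(counts.mean())
    cv = float(counts.std(ddof=1) / n_genomes) if len(counts) > 1 else 0.0
    return AGSEstimate(
        n_bases_assembly=float(total_bases),
        marker_counts=counts,
        n_genomes=n_genomes,
        cv=cv,
        reliable=cv < CV_LIMIT,
    )


def ags_series(
    marker_table: pd.DataFrame,
    total_bases: pd.Series,
    fit: bool = True,
):
    """Per-sample AGS estimates over a time series, with an anomaly fit.

    Parameters
    ----------
    marker_table : DataFrame
        Markers x samples coverage-weighted counts; columns are ISO dates.
    total_bases : Series
        Per-sample total assembled bases, aligned to the table's columns.
    fit : bool
        Also fit the month/year anomaly model to the reliable samples.

    Returns
    -------
    (frame, results) where ``frame`` has one row per sample (ags, cv,
    reliable) and ``results`` is the AnomalyResults for the AGS series over
    reliable samples (None when ``fit=False``).
    """
    rows = {}
    for sample in marker_table.columns:
        est = estimate_ags(marker_table[sample], float(total_bases[sample]))
        rows[sample] = {
            "ags": est.ags if est.reliable else np.nan,
            "cv": est.cv,
            "reliable": est.reliable,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample"
    n_unreliable = int((~frame["reliable"]).sum())
    frame.attrs["n_unreliable"] = n_unreliable
    results = None
    if fit:
        ok = frame[frame["reliable"]]
        if ok.empty:
            raise ValueError("no reliable samples to fit")
        series = pd.Series(
            ok["ags"].to_numpy(), index=pd.to_datetime(ok.index), name="ags"
        )
        results = SeasonalAnomalyModel(series, series.index).fit()
    return frame, results
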