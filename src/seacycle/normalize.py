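"""Coverage normalization: proportions, rare-feature filtering, z-scores,
and robust loess smoothing.

The observation model of shotgun metagenomics is compositional: coverage only
carries information about *relative* feature abundance, so every downstream
stage works on per-sample proportions.  Features whose mean proportion falls
below a detection floor (default 5e-5) are excluded so that the retained
matrix has almost no zeros and linear methods (PCA, OLS anomaly models)
remain appropriate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CoverageTable, ProportionTable, ZScoreTable

__all__ = ["to_proportions", "filter_rare", "zscore", "robust_loess"]

#: Features with mean relative abundance below this are excluded by default.
DEFAULT_MIN_ABUNDANCE = 5e-5


def to_proportions(table: CoverageTable) -> ProportionTable:
    """Normalize each sample's coverage to its summed total.

    Raises
    ------
    ValueError
        If any sample has zero total coverage (the sample is named).
    """
    totals = table.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"samples with zero total coverage: {', '.join(map(str, zero.index))}"
        )
    props = table.data.div(totals, axis=1)
    return ProportionTable(
        data=props,
        retained=pd.Series(True, index=props.index),
        totals=totals,
        meta=table.meta,
    )


def filter_rare(
    table: ProportionTable, threshold: float = DEFAULT_MIN_ABUNDANCE
) -> ProportionTable:
    """Flag features whose mean proportion falls below ``threshold``.

    The comparison is inclusive: a feature sitting exactly at the threshold is
    retained.  The filter criterion is the mean proportion across the whole
    series, which yields one fixed feature set for ordination and anomaly
    fitting.  Dropped features stay in ``data`` (for provenance) but are
    excluded from ``retained_data``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mean_prop = table.data.mean(axis=1)
    retained = mean_prop >= threshold
    return ProportionTable(
        data=table.data,
        retained=retained,
        totals=table.totals,
        threshold=threshold,
        meta=table.meta,
    )


def zscore(table: ProportionTable) -> ZScoreTable:
    """Standardize each retained feature to mean 0, sd 1 across samples.

    Uses the n-1 (sample) standard deviation.  Zero-variance features cannot
    be standardized; they are dropped with a warning and listed in
    ``dropped_constant``.
    """
    data = table.retained_data
    if data.shape[1] < 2:
        raise ValueError("z-scoring requires at least two samples")
    means = data.mean(axis=1)
    sds = data.std(axis=1, ddof=1)
    constant = sds <= 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance feature(s) "
            "before z-scoring",
            stacklevel=2,
        )
    keep = ~constant
    z = data.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return ZScoreTable(
        data=z,
        means=means[keep],
        sds=sds[keep],
        dropped_constant=list(data.index[constant]),
    )


def robust_loess(
    y,
    x=None,
    span: float = 0.3,
    iterations: int = 3,
):
    """Robust locally weighted regression (loess) smoother.

    Local linear fits with tri-cube weights, iterated with bisquare
    robustness weights so gross outliers are down-weighted — the smoother
    used for environmental moving averages and as the low-frequency band-pass
    filter for community time series.

    Parameters
    ----------
    y : array-like
        Series values; a :class:`pandas.Series` keeps its index.
    x : array-like, optional
        Abscissa (e.g. days since start).  Defaults to the Series index if
        datetime-like, else to 0..n-1.
    span : float
        Fraction of the data in each local window, in (0, 1].
    iterations : int
        Robustifying reweighting iterations (0 disables robustness).
    """
    index = None
    if isinstance(y, pd.Series):
        index = y.index
        if x is None:
            if isinstance(index, pd.DatetimeIndex):
                x = (index - index[0]).days.to_numpy(dtype=float)
            else:
                x = np.asarray(index, dtype=float)
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    x = np.asarray(x, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(y)
    if n < 5:
        raise ValueError("robust loess needs at least 5 points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    smoothed_sorted = _loess_sorted(xs, ys, span, iterations)
    smoothed = np.empty(n)
    smoothed[order] = smoothed_sorted
    if index is not None:
        return pd.Series(smoothed, index=index)
    return smoothed


def _loess_sorted(x, y, span, iterations):
    """Robust loess on sorted abscissa: local linear, tri-cube distance
    weights over the span*n nearest points, Cleveland bisquare robustness.

    The bisquare scale is 6x the median absolute residual; when that median
    collapses to ~0 (a majority of points fitted exactly, e.g. a constant
    series with one gross outlier) the mean absolute residual takes over so
    the reweighting stays defined and the outlier is still rejected.
    """
    n = len(y)
    k = min(n, max(2, int(np.ceil(span * n))))
    robust = np.ones(n)
    fitted = y.copy()
    for it in range(iterations + 1):
        lo = 0
        for i in range(n):
            # slide the k-window to the nearest neighbours of x[i]
            while lo + k < n and x[i] - x[lo] > x[lo + k] - x[i]:
                lo += 1
            sl = slice(lo, lo + k)
            xw, yw = x[sl], y[sl]
            d = np.abs(xw - x[i])
            dmax = d.max()
            tri = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
            w = np.clip(tri, 0.0, None) * robust[sl]
            if w.sum() <= 0:
                w = np.clip(tri, 0.0, None)  # all neighbours rejected
            sw = w.sum()
            xm = (w * xw).sum() / sw
            ym = (w * yw).sum() / sw
            sxx = (w * (xw - xm) ** 2).sum()
            b = (w * (xw - xm) * (yw - ym)).sum() / sxx if sxx > 0 else 0.0
            fitted[i] = ym + b * (x[i] - xm)
        if it == iterations:
            break
        resid = y - fitted
        scale = np.median(np.abs(resid))
        mean_abs = np.mean(np.abs(resid))
        if scale <= 1e-9 * mean_abs:
            scale = mean_abs
        if scale <= 0:
            break  # perfect fit
        robust = np.clip(1 - (resid / (6 * scale)) ** 2, 0.0, 1.0) ** 2
    return fitted
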