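"""Seasonal / interannual anomaly decomposition.

Each feature's time series (a z-scored taxon or gene-family proportion, an
environmental variable, a community-aggregated trait) is modelled as

    y_t = mu + alpha_{month(t)} + beta_{year(t)} + e_t

an ordinary least-squares fit with 12 monthly and one-per-observed-year
categorical factors, no interaction, under sum-to-zero (effects) coding.  The
fitted monthly effects are the *seasonal anomaly* (deviation from the grand
mean attributable to a calendar month) and the yearly effects the
*interannual anomaly*.  Sequential (Type-I) sums of squares, month entered
first, partition the total variance into seasonal, interannual and residual
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeasonalAnomalyModel",
    "AnomalyResults",
    "AnomalyResultsSet",
    "fit_anomaly",
    "scale_anomaly",
    "order_by_peak",
    "env_variance_explained",
]

MONTHS = np.arange(1, 13)


def scale_anomaly(effects) -> np.ndarray:
    """Scale a vector of effects to [-1, 1] by its maximum absolute value.

    An all-zero vector is returned unchanged (no division).  NaN entries
    (non-estimable levels) are ignored when finding the maximum.
    """
    effects = np.asarray(effects, dtype=float)
    with np.errstate(invalid="ignore"):
        peak = np.nanmax(np.abs(effects)) if effects.size else 0.0
    if not np.isfinite(peak) or peak == 0:
        return effects.copy()
    return effects / peak


def _effects_design(levels: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Sum-to-zero (effects) coded dummy block for ``observed`` level values.

    One column per level except the last; the last level is coded -1 in every
    column so the fitted effects sum to zero over observed levels.
    """
    k = len(levels)
    cols = np.zeros((len(observed), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[observed == lev, j] = 1.0
    cols[observed == levels[-1], :] = -1.0
    return cols


class SeasonalAnomalyModel:
    """OLS month + year categorical decomposition of one or many series.

    Parameters
    ----------
    data : Series or DataFrame
        One time series, or a features-by-samples frame (each row one
        series).  Column order must match ``dates``.
    dates : array-like of datetime
        Sample collection dates; only the calendar month and year are used.
    ss_order : tuple
        Order in which factors enter the sequential sum-of-squares
        partition.  Month first by default: the seasonal signal dominates
        these series, and Type-I SS attributes shared variance to the factor
        entered first.
    """

    def __init__(self, data, dates, ss_order: tuple[str, str] = ("month", "year")):
        if isinstance(data, pd.Series):
            self._single = True
            self.names = [data.name if data.name is not None else "series"]
            y = data.to_numpy(dtype=float)[None, :]
        else:
            self._single = False
            frame = pd.DataFrame(data)
            self.names = list(frame.index)
            y = frame.to_numpy(dtype=float)
        dates = pd.DatetimeIndex(pd.to_datetime(dates))
        if y.shape[1] != len(dates):
            raise ValueError("data columns and dates must align")
        if np.isnan(y).any():
            raise ValueError("missing values in series; drop missing-date rows first")
        if set(ss_order) != {"month", "year"}:
            raise ValueError("ss_order must be a permutation of ('month', 'year')")
        self.y = y
        self.dates = dates
        self.ss_order = tuple(ss_order)
        self.months = dates.month.to_numpy()
        self.years = dates.year.to_numpy()
        self.month_levels = np.unique(self.months)
        self.year_levels = np.unique(self.years)
        if len(self.month_levels) < 2 or len(self.year_levels) < 2:
            raise ValueError(
                "need at least two distinct months and two distinct years"
            )
        if len(self.month_levels) < 12:
            missing = sorted(set(MONTHS) - set(self.month_levels))
            warnings.warn(
                f"months with no observations dropped from design: {missing}; "
                "their effects are not estimable",
                stacklevel=2,
            )

    # -- fitting ---------------------------------------------------------

    def fit(self):
        """Fit by OLS; returns :class:`AnomalyResults` (single series) or
        :class:`AnomalyResultsSet` (many series, one shared design solve)."""
        n = self.y.shape[1]
        month_block = _effects_design(self.month_levels, self.months)
        year_block = _effects_design(self.year_levels, self.years)
        blocks = {"month": month_block, "year": year_block}
        intercept = np.ones((n, 1))

        # nested designs for sequential (Type-I) SS: 1 -> +first -> +both
        X1 = np.hstack([intercept, blocks[self.ss_order[0]]])
        X2 = np.hstack([X1, blocks[self.ss_order[1]]])

        Y = self.y.T  # samples x features
        ybar = Y.mean(axis=0)
        rss0 = ((Y - ybar) ** 2).sum(axis=0)
        rss1 = self._rss(X1, Y)
        beta2, rss2 = self._solve(X2, Y)

        ss = {
            self.ss_order[0]: rss0 - rss1,
            self.ss_order[1]: rss1 - rss2,
        }
        resid = Y - X2 @ beta2

        # recover full effect vectors from the full-model coefficients; the
        # coefficient layout of X2 depends on ss_order
        p_first = blocks[self.ss_order[0]].shape[1]
        coef_first = beta2[1 : 1 + p_first]
        coef_second = beta2[1 + p_first :]
        coefs = {self.ss_order[0]: coef_first, self.ss_order[1]: coef_second}

        month_eff = self._expand(coefs["month"], self.month_levels, MONTHS)
        year_eff = self._expand(coefs["year"], self.year_levels, self.year_levels)

        results = []
        for i, name in enumerate(self.names):
            results.append(
                AnomalyResults(
                    name=name,
                    intercept=float(beta2[0, i]),
                    monthly_effects=pd.Series(month_eff[:, i], index=MONTHS),
                    yearly_effects=pd.Series(year_eff[:, i], index=self.year_levels),
                    residuals=pd.Series(resid[:, i], index=self.dates),
                    ss_month=float(ss["month"][i]),
                    ss_year=float(ss["year"][i]),
                    ss_residual=float(rss2[i]),
                    ss_total=float(rss0[i]),
                    ss_order=self.ss_order,
                )
            )
        if self._single:
            return results[0]
        return AnomalyResultsSet(results)

    @staticmethod
    def _solve(X, Y):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        rss = ((Y - X @ beta) ** 2).sum(axis=0)
        return beta, rss

    @classmethod
    def _rss(cls, X, Y):
        return cls._solve(X, Y)[1]

    @staticmethod
    def _expand(coef, levels, all_levels):
        """Coefficients for levels[:-1] -> full effect vectors over
        ``all_levels`` with the last observed level reconstructed as minus the
        sum and unobserved levels as NaN."""
        k, p = len(all_levels), coef.shape[1]
        out = np.full((k, p), np.nan)
        pos = {lev: i for i, lev in enumerate(all_levels)}
        for j, lev in enumerate(levels[:-1]):
            out[pos[lev]] = coef[j]
        out[pos[levels[-1]]] = -coef.sum(axis=0)
        return out


@dataclass
class AnomalyResults:
    """Fitted month/year anomaly decomposition for one series."""

    name: object
    intercept: float
    monthly_effects: pd.Series  # index 1..12, NaN where not estimable
    yearly_effects: pd.Series  # index = observed years
    residuals: pd.Series
    ss_month: float
    ss_year: float
    ss_residual: float
    ss_total: float
    ss_order: tuple = ("month", "year")

    @property
    def peak_month(self) -> int:
        """Calendar month of the maximum monthly effect."""
        return int(self.monthly_effects.idxmax())

    @property
    def peak_year(self) -> int:
        return int(self.yearly_effects.idxmax())

    @property
    def scaled_monthly(self) -> pd.Series:
        return pd.Series(
            scale_anomaly(self.monthly_effects.to_numpy()),
            index=self.monthly_effects.index,
        )

    @property
    def scaled_yearly(self) -> pd.Series:
        return pd.Series(
            scale_anomaly(self.yearly_effects.to_numpy()),
            index=self.yearly_effects.index,
        )

    @property
    def circular_phase(self) -> float:
        """Phase (in months, [0, 12)) of a single-harmonic cosine fitted to
        the monthly effects; the peak-ordering tie-break key."""
        eff = self.monthly_effects.dropna()
        theta = 2 * np.pi * (eff.index.to_numpy() - 1) / 12
        a = np.nansum(eff.to_numpy() * np.cos(theta))
        b = np.nansum(eff.to_numpy() * np.sin(theta))
        phase = np.arctan2(b, a) * 12 / (2 * np.pi)
        return float(phase % 12)

    def variance_fractions(self) -> tuple[float, float, float]:
        """(seasonal, interannual, residual) fractions of total SS."""
        if self.ss_total <= 0:
            raise ValueError("variance fractions undefined for a constant series")
        return (
            self.ss_month / self.ss_total,
            self.ss_year / self.ss_total,
            self.ss_residual / self.ss_total,
        )

    def summary(self) -> str:
        sf, yf, rf = self.variance_fractions() if self.ss_total > 0 else (0, 0, 0)
        lines = [
            f"Seasonal/interannual anomaly decomposition: {self.name}",
            f"  n = {len(self.residuals)}, grand mean = {self.intercept:.6g}",
            f"  SS partition ({'->'.join(self.ss_order)}): "
            f"month {self.ss_month:.4g}, year {self.ss_year:.4g}, "
            f"residual {self.ss_residual:.4g}, total {self.ss_total:.4g}",
            f"  variance fractions: seasonal {sf:.3f}, "
            f"interannual {yf:.3f}, residual {rf:.3f}",
            f"  peak month = {self.peak_month}, peak year = {self.peak_year}",
        ]
        return "\n".join(lines)


class AnomalyResultsSet:
    """Anomaly fits for a collection of features (one shared design)."""

    def __init__(self, results: list[AnomalyResults]):
        self.results = results
        self._by_name = {r.name: r for r in results}

    def __len__(self):
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, name):
        if isinstance(name, int):
            return self.results[name]
        return self._by_name[name]

    def monthly_effects(self) -> pd.DataFrame:
        """Features x 12 frame of monthly effects."""
        return pd.DataFrame(
            {r.name: r.monthly_effects for r in self.results}
        ).T

    def yearly_effects(self) -> pd.DataFrame:
        return pd.DataFrame({r.name: r.yearly_effects for r in self.results}).T

    def frame(self) -> pd.DataFrame:
        """One row per feature: intercept, effects, SS fractions, peaks."""
        rows = {}
        for r in self.results:
            row = {"intercept": r.intercept}
            row.update({f"month_{m}": v for m, v in r.monthly_effects.items()})
            row.update({f"year_{y}": v for y, v in r.yearly_effects.items()})
            sf, yf, rf = r.variance_fractions()
            row.update(
                seasonal_fraction=sf,
                interannual_fraction=yf,
                residual_fraction=rf,
                peak_month=r.peak_month,
                peak_year=r.peak_year,
            )
            rows[r.name] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def fit_anomaly(series, dates=None, **kwargs):
    """Convenience wrapper: fit the month/year anomaly model to one series
    (or a features-by-samples frame).  ``dates`` defaults to the Series
    index when datetime-like."""
    if dates is None:
        if isinstance(series, (pd.Series, pd.DataFrame)) and isinstance(
            series.index if isinstance(series, pd.Series) else series.columns,
            pd.DatetimeIndex,
        ):
            dates = series.index if isinstance(series, pd.Series) else series.columns
        else:
            raise ValueError("dates required unless the series is date-indexed")
    return SeasonalAnomalyModel(series, dates, **kwargs).fit()


def order_by_peak(fits, by: str = "month") -> list:
    """Order features by peak month (or peak positive year).

    Ties on the integer peak are broken by the circular phase of a
    single-harmonic cosine fitted to the monthly effects, which resolves
    features peaking in the same calendar month by their sub-monthly phase.
    """
    results = list(fits)
    if not results:
        raise ValueError("no fits to order")
    if by == "month":
        keyed = sorted(results, key=lambda r: (r.peak_month, r.circular_phase))
    elif by == "year":
        keyed = sorted(results, key=lambda r: (r.peak_year, r.circular_phase))
    else:
        raise ValueError("by must be 'month' or 'year'")
    return [r.name for r in keyed]


def env_variance_explained(
    yearly_effects: pd.DataFrame,
    env_yearly: pd.DataFrame,
    cond_tol: float = 1e8,
) -> float:
    """Fraction of features' interannual variance explained by environmental
    covariates.

    Each feature's yearly-effect vector is regressed (OLS, with intercept) on
    the environmental yearly effects; the statistic is the redundancy-style
    ratio sum(explained SS) / sum(total SS) pooled over features.

    Parameters
    ----------
    yearly_effects : DataFrame
        Features x years.
    env_yearly : DataFrame
        Years x covariates (e.g. temperature and nitrate yearly effects).
    """
    years = yearly_effects.columns
    env = env_yearly.loc[years]
    if env.shape[1] < 2:
        raise ValueError("need at least two environmental covariates")
    if len(years) < 4:
        raise ValueError("need at least four years")
    X = np.column_stack([np.ones(len(years)), env.to_numpy(dtype=float)])
    if np.linalg.cond(X) > cond_tol:
        raise ValueError("environmental covariates are collinear")
    Y = yearly_effects.to_numpy(dtype=float).T  # years x features
    Yc = Y - Y.mean(axis=0)
    tss = (Yc**2).sum()
    if tss <= 0:
        raise ValueError("yearly effects have zero variance")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    rss = ((Y - X @ beta) ** 2).sum()
    return float((tss - rss) / tss)
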