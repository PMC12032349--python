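"""Annotation keyword screen.

Free-text gene annotations are tokenized into keywords, each keyword is
treated like a unit of biodiversity whose per-sample value is the summed
relative abundance of the genes mentioning it, and keywords are ranked by
the seasonal and annual variance fractions of their anomaly fits.  The
ranking nominates gene families for trait curation (e.g. "iron", "urea",
"phosphatase" surface as strongly seasonal keywords).

Tokenization is deterministic by default: lowercased alphabetic tokens of
length >= 3 with stop-words removed, each keyword counted once per gene.  A
part-of-speech filter (keep nouns and verbs only) can be plugged in via the
``pos_filter`` hook when a tagger is available; both paths share the same
downstream contract.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .anomaly import AnomalyResults, SeasonalAnomalyModel
from .containers import ProportionTable

__all__ = ["STOPWORDS", "KeywordSeries", "extract_keywords", "keyword_series", "rank_keywords"]

#: Versioned stop-word list: English function words plus annotation
#: boilerplate that carries no biochemical signal.
STOPWORDS = frozenset(
    """
    the a an and or not of in on for with within without to from into by as at
    is are was were be been being has have had this that these those its it
    via under over between among per non all any other same both each
    protein proteins putative predicted probable hypothetical uncharacterized
    unknown unnamed conserved
    """.split()
)

_TOKEN = re.compile(r"[a-z]{3,}")


def extract_keywords(annotations: dict, pos_filter=None) -> dict:
    """Build the keyword -> gene-ID index from free-text annotations.

    Parameters
    ----------
    annotations : mapping gene ID -> description string
    pos_filter : callable, optional
        ``f(description) -> iterable of words`` restricting tokens (e.g. a
        part-of-speech tagger keeping nouns and verbs); applied before the
        deterministic token-shape and stop-word filters.

    Keywords are counted at most once per gene (binary occurrence), so
    verbose annotations do not overweight a gene.
    """
    if not annotations:
        raise ValueError("annotations are empty")
    index: dict[str, set] = {}
    for gene, text in annotations.items():
        if not text:
            continue
        source = " ".join(pos_filter(text)) if pos_filter is not None else text
        tokens = set(_TOKEN.findall(source.lower())) - STOPWORDS
        for tok in tokens:
            index.setdefault(tok, set()).add(gene)
    return index


@dataclass
class KeywordSeries:
    """One keyword's coverage-weighted time series and its anomaly fit."""

    keyword: str
    values: pd.Series  # per-sample summed member-gene proportion
    genes: list
    fit: AnomalyResults | None = field(default=None, repr=False)

    @property
    def seasonal_fraction(self) -> float:
        return self.fit.variance_fractions()[0]

    @property
    def annual_fraction(self) -> float:
        return self.fit.variance_fractions()[1]


def keyword_series(
    index: dict, proportions, fit: bool = True
) -> dict:
    """Per-sample keyword values: the sum of member-gene proportions.

    Parameters
    ----------
    index : keyword -> set of gene IDs (from :func:`extract_keywords`)
    proportions : ProportionTable or features-by-samples DataFrame with
        ISO-date columns.
    fit : bool
        Attach the month/year anomaly fit to each series (one vectorized
        model solve for all keywords).
    """
    if isinstance(proportions, ProportionTable):
        frame = proportions.retained_data
    else:
        frame = pd.DataFrame(proportions)
    known = set(frame.index)
    rows = {}
    members = {}
    for kw, genes in index.items():
        present = sorted(g for g in genes if g in known)
        dropped = genes - known
        if dropped:
            warnings.warn(
                f"keyword {kw!r}: {len(dropped)} gene(s) absent from the "
                "table dropped",
                stacklevel=2,
            )
        if not present:
            continue
        rows[kw] = frame.loc[present].sum(axis=0)
        members[kw] = present
    if not rows:
        return {}
    values = pd.DataFrame(rows).T  # keywords x samples
    fits = {}
    if fit:
        dates = pd.to_datetime(values.columns)
        fits = {
            r.name: r for r in SeasonalAnomalyModel(values, dates).fit()
        }
    return {
        kw: KeywordSeries(
            keyword=kw,
            values=values.loc[kw],
            genes=members[kw],
            fit=fits.get(kw),
        )
        for kw in values.index
    }


def rank_keywords(series: dict, top_n: int | None = None):
    """Rank keywords by seasonal and by annual variance fraction.

    Returns two DataFrames (seasonal-ranked, annual-ranked), each with the
    variance fractions, the peak month/year and the member genes attached
    for downstream trait curation.  ``top_n`` larger than the number of
    keywords returns the full list.
    """
    records = []
    for kw, s in series.items():
        if s.fit is None:
            raise ValueError(f"keyword {kw!r} has no anomaly fit")
        sf, af, rf = s.fit.variance_fractions()
        records.append(
            {
                "keyword": kw,
                "seasonal_fraction": sf,
                "annual_fraction": af,
                "residual_fraction": rf,
                "peak_month": s.fit.peak_month,
                "peak_year": s.fit.peak_year,
                "genes": ",".join(s.genes),
            }
        )
    frame = pd.DataFrame.from_records(records).set_index("keyword")
    seasonal = frame.sort_values("seasonal_fraction", ascending=False)
    annual = frame.sort_values("annual_fraction", ascending=False)
    if top_n is not None:
        seasonal = seasonal.head(top_n)
        annual = annual.head(top_n)
    return seasonal, annual
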