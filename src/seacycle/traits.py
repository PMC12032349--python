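"""Community-aggregated biogeochemical traits.

A trait is a curated set of gene families tied to one biogeochemical
function — iron, nitrogen or phosphorus stress (KEGG Orthologs) or organic
matter degradation (Pfam CAZymes).  The community-aggregated trait
proportion in a sample is the summed coverage of all member genes divided by
the total annotated coverage of the table, so traits live on the same
relative scale as individual features and inherit the anomaly machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .anomaly import AnomalyResults, SeasonalAnomalyModel
from .containers import CoverageTable
from .gene_sets import TRAIT_GENE_SETS

__all__ = [
    "TraitDefinition",
    "TraitSeries",
    "default_trait_definitions",
    "load_trait_definitions",
    "dump_trait_definitions",
    "aggregate_trait",
    "trait_anomalies",
    "env_trait_correlation",
    "trait_antiphase_report",
]


@dataclass
class TraitDefinition:
    """Named gene set mapping annotation IDs to a biogeochemical function."""

    name: str
    system: str  # "KO" or "Pfam"
    genes: dict  # gene ID -> free-text function category

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("member gene IDs must be unique")

    @property
    def gene_ids(self) -> list:
        return list(self.genes)


def default_trait_definitions() -> dict:
    """The built-in Fe/N/P-stress and carbon-degradation trait sets."""
    return {
        name: TraitDefinition(name, system, dict(genes))
        for name, (system, genes) in TRAIT_GENE_SETS.items()
    }


def load_trait_definitions(path) -> dict:
    """Read trait definitions from YAML.

    Schema: ``{trait: {system: KO|Pfam, genes: [{id: ..., function: ...}]}}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        genes = {g["id"]: g.get("function", "") for g in entry["genes"]}
        out[name] = TraitDefinition(name, entry["system"], genes)
    return out


def dump_trait_definitions(definitions: dict, path) -> None:
    raw = {
        name: {
            "system": d.system,
            "genes": [{"id": g, "function": f} for g, f in d.genes.items()],
        }
        for name, d in definitions.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TraitSeries:
    """Per-sample aggregated proportion of one trait, plus per-function
    sub-series for the biochemical categories inside the trait."""

    definition: TraitDefinition
    proportions: pd.Series  # per sample, in [0, 1]
    sub_series: pd.DataFrame  # function category x samples
    missing_genes: list = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(pd.to_datetime(self.proportions.index))


def aggregate_trait(
    table: CoverageTable, definition: TraitDefinition
) -> TraitSeries:
    """Sum member-gene coverage and normalize by total annotated coverage.

    Member genes absent from the table are recorded on the result; if none
    are present the trait cannot be computed and an error lists the missing
    IDs.  Sub-series group member genes by their biochemical function
    category.
    """
    present = [g for g in definition.gene_ids if g in table.data.index]
    missing = [g for g in definition.gene_ids if g not in table.data.index]
    if not present:
        raise ValueError(
            f"no member gene of trait {definition.name!r} present; "
            f"missing: {', '.join(missing)}"
        )
    totals = table.data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples with zero total coverage")
    member = table.data.loc[present]
    proportions = member.sum(axis=0) / totals
    proportions.name = definition.name
    functions = pd.Series({g: definition.genes[g] for g in present})
    sub = member.groupby(functions).sum().div(totals, axis=1)
    return TraitSeries(
        definition=definition,
        proportions=proportions,
        sub_series=sub,
        missing_genes=missing,
    )


def trait_anomalies(series: TraitSeries) -> AnomalyResults:
    """Month/year anomaly decomposition of the trait proportion series."""
    y = pd.Series(
        series.proportions.to_numpy(), index=series.dates, name=series.name
    )
    return SeasonalAnomalyModel(y, y.index).fit()


def env_trait_correlation(
    trait_yearly: pd.Series,
    env_yearly: pd.DataFrame,
    negate: tuple = ("nitrate",),
) -> pd.Series:
    """Spearman correlation of a trait's interannual anomalies with
    environmental interannual anomalies.

    Covariates named in ``negate`` are multiplied by -1 before correlating,
    turning e.g. nitrate concentration into a nitrate-stress axis (low
    nitrate = high stress).  Requires at least four overlapping years.
    """
    years = trait_yearly.index.intersection(env_yearly.index)
    if len(years) < 4:
        raise ValueError("need at least four overlapping years")
    t = trait_yearly.loc[years]
    out = {}
    for col in env_yearly.columns:
        e = env_yearly.loc[years, col]
        if col in negate:
            e = -e
        rho, _ = stats.spearmanr(t, e)
        out[col] = float(rho)
    return pd.Series(out, name=trait_yearly.name)


def trait_antiphase_report(yearly_by_trait: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of trait interannual anomalies.

    Input is traits x years (one row of yearly effects per trait); negative
    off-diagonal entries indicate anti-phased interannual succession, e.g.
    Fe-stress vs N-stress communities favoured in opposite ENSO phases.
    """
    if yearly_by_trait.shape[0] < 2:
        raise ValueError("need at least two traits")
    names = list(yearly_by_trait.index)
    k = len(names)
    rho = np.eye(k)
    arr = yearly_by_trait.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            r, _ = stats.spearmanr(arr[i], arr[j])
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=names, columns=names)
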