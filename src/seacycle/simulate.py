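"""Synthetic multi-year marine community time series with known ground truth.

The simulator emulates the statistical regime of a coastal ocean microbiome
time series: roughly fortnightly-to-weekly sampling over eleven years, an
annual temperature sinusoid with nutrients oscillating in anti-phase
(upwelling-fed winters, oligotrophic summers), ENSO-like multi-year
anomalies, and a community of taxa split into two ecological guilds —
winter/spring-peaking "copiotrophs" with large genomes carrying iron-stress
and carbon-degradation genes, and summer/fall-peaking "oligotrophs" with
small streamlined genomes carrying N/P-stress genes.

Each taxon's latent log-abundance is

    l_it = b_i + A_i cos(2*pi*(month_t - phi_i)/12) + s_i * ENSO(year_t) + e_it

with AR(1) noise e; relative abundances are the per-sample softmax and reads
are drawn compositionally (multinomial, or Dirichlet-multinomial when
overdispersion > 0).  Every generated table is a deterministic function of
the configuration seed, and the :class:`SyntheticTruth` object carries the
injected parameters for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CoverageTable
from .gene_sets import SINGLE_COPY_MARKERS, TRAIT_GENE_SETS
from .taxonomy import ContigRecord, TaxonomyPath

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_environment",
    "simulate_community",
    "simulate_contigs",
    "simulate_marker_counts",
]

#: Annual-mean Ocean Nino Index-like values, 2011-2021: La Nina at both ends,
#: a strong El Nino mid-series.
DEFAULT_ENSO = {
    2011: -0.7, 2012: -0.2, 2013: -0.3, 2014: 0.2, 2015: 1.6, 2016: 0.5,
    2017: -0.3, 2018: 0.2, 2019: 0.4, 2020: -0.9, 2021: -0.9,
}

_PHYLA = {
    "copiotroph": [
        ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales"),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Cellvibrionales"),
    ],
    "oligotroph": [
        ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales"),
        ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales"),
    ],
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic community time series."""

    n_taxa: int
    taxon_names: list
    lineages: list  # GTDB-style strings, one per taxon
    start_date: str = "2011-01-01"
    end_date: str = "2021-12-31"
    sampling_interval_days: float = 14.0
    baseline: np.ndarray | None = None
    seasonal_amplitude: np.ndarray | None = None
    seasonal_peak_month: np.ndarray | None = None
    enso_series: dict = field(default_factory=lambda: dict(DEFAULT_ENSO))
    enso_sensitivity: np.ndarray | None = None
    genome_size: np.ndarray | None = None
    genes_per_taxon: dict = field(default_factory=dict)
    guild: list | None = None  # "copiotroph"/"oligotroph" per taxon
    total_reads: int = 1_000_000
    overdispersion: float = 0.0
    noise_sd: float = 0.5
    noise_rho: float = 0.9
    # environmental forcing
    temp_mean: float = 17.0
    temp_amplitude: float = 4.0
    temp_peak_month: int = 8
    enso_temp_scale: float = 1.0
    env_noise_sd: float = 0.3
    marker_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        z = np.zeros(self.n_taxa)
        if self.baseline is None:
            self.baseline = z.copy()
        if self.seasonal_amplitude is None:
            self.seasonal_amplitude = np.ones(self.n_taxa)
        if self.seasonal_peak_month is None:
            self.seasonal_peak_month = np.tile([2, 8], self.n_taxa)[: self.n_taxa]
        if self.enso_sensitivity is None:
            self.enso_sensitivity = z.copy()
        if self.genome_size is None:
            self.genome_size = np.full(self.n_taxa, 3e6)
        for name in (
            "baseline",
            "seasonal_amplitude",
            "seasonal_peak_month",
            "enso_sensitivity",
            "genome_size",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if len(self.taxon_names) != self.n_taxa or len(self.lineages) != self.n_taxa:
            raise ValueError("taxon_names/lineages must have n_taxa entries")
        months = self.seasonal_peak_month
        if ((months < 1) | (months > 12)).any():
            raise ValueError("seasonal_peak_month must be within 1..12")
        if (self.genome_size <= 0).any():
            raise ValueError("genome sizes must be positive")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")
        if self.sampling_interval_days <= 0:
            raise ValueError("sampling_interval_days must be positive")
        for arr in (self.baseline, self.seasonal_amplitude, self.enso_sensitivity):
            if len(arr) != self.n_taxa:
                raise ValueError("per-taxon arrays must have n_taxa entries")

    # -- construction ----------------------------------------------------

    @classmethod
    def default(cls, n_taxa: int = 20, seed: int = 0, **overrides):
        """Guild-structured default community.

        Half the taxa are winter/spring-peaking copiotrophs (genomes
        3-6 Mbp, negatively ENSO-sensitive — favoured in cool La Nina
        years) carrying Fe-stress and carbon-degradation genes; half are
        summer/fall-peaking oligotrophs (1.2-2 Mbp, positively
        ENSO-sensitive) carrying N- and P-stress genes.  All taxa carry the
        139 single-copy markers and a shared housekeeping gene pool.
        """
        rng = np.random.default_rng([seed, 77])
        n_cop = n_taxa // 2
        guild = ["copiotroph"] * n_cop + ["oligotroph"] * (n_taxa - n_cop)
        names, lineages = [], []
        peak, sens, genome, amp = [], [], [], []
        genes: dict[str, set] = {}
        housekeeping = [f"K1{j:04d}" for j in range(40)]
        cop_traits = set(TRAIT_GENE_SETS["Fe_stress"][1]) | set(
            TRAIT_GENE_SETS["C_degradation"][1]
        )
        oli_traits = set(TRAIT_GENE_SETS["N_stress"][1]) | set(
            TRAIT_GENE_SETS["P_stress"][1]
        )
        for i, g in enumerate(guild):
            name = f"{'Cop' if g == 'copiotroph' else 'Oli'}{i + 1:02d}"
            names.append(name)
            dom, phy, cla, order = _PHYLA[g][i % 2]
            lineages.append(
                f"d__{dom};p__{phy};c__{cla};o__{order};f__{name}aceae"
            )
            if g == "copiotroph":
                peak.append(int(rng.integers(1, 5)))  # winter/spring
                sens.append(-float(rng.uniform(0.4, 0.8)))
                genome.append(float(rng.uniform(3e6, 6e6)))
                trait_pool = cop_traits
            else:
                peak.append(int(rng.integers(7, 11)))  # summer/fall
                sens.append(float(rng.uniform(0.4, 0.8)))
                genome.append(float(rng.uniform(1.2e6, 2e6)))
                trait_pool = oli_traits
            amp.append(float(rng.uniform(0.8, 1.5)))
            # iterate in sorted order: set order is hash-seed dependent and
            # would break cross-process reproducibility of the rng stream
            carried = {gid for gid in sorted(trait_pool) if rng.random() < 0.8}
            hk = {h for h in housekeeping if rng.random() < 0.75}
            accessory = {f"K2{i:02d}{j:02d}" for j in range(5)}
            genes[name] = carried | hk | accessory | set(SINGLE_COPY_MARKERS)
        # guarantee every trait gene occurs in at least one taxon
        for trait, (_, members) in TRAIT_GENE_SETS.items():
            pool = range(n_cop) if trait in ("Fe_stress", "C_degradation") else range(
                n_cop, n_taxa
            )
            for gid in members:
                if not any(gid in genes[names[i]] for i in pool):
                    genes[names[next(iter(pool))]].add(gid)
        kwargs = dict(
            n_taxa=n_taxa,
            taxon_names=names,
            lineages=lineages,
            seasonal_amplitude=np.array(amp),
            seasonal_peak_month=np.array(peak),
            enso_sensitivity=np.array(sens),
            genome_size=np.array(genome),
            genes_per_taxon=genes,
            guild=guild,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    # -- calendar --------------------------------------------------------

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_date, self.end_date, freq=f"{int(self.sampling_interval_days)}D"
        )

    def enso_at(self, years: np.ndarray) -> np.ndarray:
        return np.array([self.enso_series.get(int(y), 0.0) for y in years])


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated tables, for recovery tests."""

    latent: pd.DataFrame  # taxa x samples latent log-abundance
    rel_abundance: pd.DataFrame  # taxa x samples, columns sum to 1
    counts: pd.DataFrame  # taxa x samples observed read counts
    monthly_effects: pd.DataFrame  # taxa x 12 injected seasonal anomaly
    yearly_effects: pd.DataFrame  # taxa x observed years, centered
    gene_monthly_effects: pd.DataFrame  # gene families x 12 (carrier-weighted)
    ags: pd.Series  # per-sample abundance-weighted mean genome size (bp)
    genome_size: pd.Series  # per-taxon genome size (bp)


def _seasonal(month, amplitude, peak_month):
    return amplitude * np.cos(2 * np.pi * (month - peak_month) / 12.0)


def _ar1(rng, shape, sd, rho):
    n_series, n_t = shape
    eps = np.empty(shape)
    eps[:, 0] = rng.normal(0, sd, n_series)
    innov = rng.normal(0, sd * np.sqrt(1 - rho**2), (n_series, n_t - 1))
    for t in range(1, n_t):
        eps[:, t] = rho * eps[:, t - 1] + innov[:, t - 1]
    return eps


def simulate_environment(config: SimulationConfig) -> pd.DataFrame:
    """Environmental covariate series at the community sampling dates.

    Temperature is an annual sinusoid (default August peak) plus the yearly
    ENSO anomaly and noise; nitrate and phosphate oscillate in anti-phase
    with temperature (cool upwelling season is nutrient-replete);
    chlorophyll and POC follow a spring-bloom cycle, and C:N / C:P / N:P
    ratios wander around Redfield stoichiometry.
    """
    dates = config.dates
    if (dates[-1] - dates[0]).days < 365:
        raise ValueError("date range must span at least one year")
    rng = np.random.default_rng([config.seed, 1])
    month = dates.month.to_numpy()
    enso = config.enso_at(dates.year.to_numpy())
    n = len(dates)

    temp = (
        config.temp_mean
        + _seasonal(month, config.temp_amplitude, config.temp_peak_month)
        + config.enso_temp_scale * enso
        + rng.normal(0, config.env_noise_sd, n)
    )
    temp_anom = temp - np.mean(temp)
    nitrate = np.clip(2.0 - 0.45 * temp_anom + rng.normal(0, 0.15, n), 0.0, None)
    phosphate = np.clip(
        0.25 - 0.03 * temp_anom + rng.normal(0, 0.02, n), 0.0, None
    )
    chlorophyll = np.clip(
        1.5 + 1.0 * np.cos(2 * np.pi * (month - 4) / 12.0)
        - 0.3 * enso
        + rng.normal(0, 0.2, n),
        0.05,
        None,
    )
    poc = np.clip(8.0 + 3.0 * chlorophyll + rng.normal(0, 1.0, n), 0.5, None)
    c_n = 6.6 + 0.08 * temp_anom + rng.normal(0, 0.2, n)
    c_p = 106.0 + 2.0 * temp_anom + rng.normal(0, 3.0, n)
    n_p = c_p / c_n
    return pd.DataFrame(
        {
            "temperature": temp,
            "nitrate": nitrate,
            "phosphate": phosphate,
            "chlorophyll": chlorophyll,
            "poc": poc,
            "c_n": c_n,
            "c_p": c_p,
            "n_p": n_p,
            "oni": enso,
        },
        index=dates,
    )


def _latent(config: SimulationConfig, rng) -> np.ndarray:
    dates = config.dates
    month = dates.month.to_numpy()
    enso = config.enso_at(dates.year.to_numpy())
    det = (
        config.baseline[:, None]
        + _seasonal(
            month[None, :],
            config.seasonal_amplitude[:, None],
            config.seasonal_peak_month[:, None],
        )
        + config.enso_sensitivity[:, None] * enso[None, :]
    )
    if config.noise_sd > 0:
        det = det + _ar1(
            rng, (config.n_taxa, len(dates)), config.noise_sd, config.noise_rho
        )
    return det


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max(axis=0))
    return z / z.sum(axis=0)


def _system_of(gene_id: str) -> str:
    if gene_id.startswith("K"):
        return "KO"
    if gene_id.startswith("PF"):
        return "Pfam"
    if gene_id.startswith("COG"):
        return "COG"
    if gene_id.startswith("TIGR"):
        return "TIGRfam"
    return "other"


def simulate_community(
    config: SimulationConfig,
) -> tuple[dict, SyntheticTruth]:
    """Simulate read-count coverage tables at every classification level.

    Returns a mapping of classification system ("family", plus one table per
    functional system present in ``genes_per_taxon``) to
    :class:`~seacycle.containers.CoverageTable`, and the
    :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng([config.seed, 2])
    dates = config.dates
    cols = [d.strftime("%Y-%m-%d") for d in dates]
    latent = _latent(config, rng)
    rel = _softmax(latent)

    counts = np.empty_like(rel)
    for t in range(rel.shape[1]):
        p = rel[:, t]
        if config.overdispersion > 0:
            p = rng.dirichlet(p / config.overdispersion)
        counts[:, t] = rng.multinomial(config.total_reads, p)

    names = config.taxon_names
    counts_df = pd.DataFrame(counts, index=names, columns=cols)
    rel_df = pd.DataFrame(rel, index=names, columns=cols)
    latent_df = pd.DataFrame(latent, index=names, columns=cols)

    # family-level table: one family per taxon lineage
    families = [TaxonomyPath.from_string(s).at("family") for s in config.lineages]
    fam_data = counts_df.copy()
    fam_data.index = families
    fam_data = fam_data.groupby(level=0).sum()
    fam_lineage = {}
    for fam, lin in zip(families, config.lineages):
        fam_lineage.setdefault(fam, lin)
    fam_meta = pd.DataFrame(
        {"system": "family", "lineage": pd.Series(fam_lineage)},
        index=fam_data.index,
    )
    tables = {"family": CoverageTable(fam_data, fam_meta)}

    # gene-family tables: coverage of gene g = sum of carrier taxon coverage
    all_genes = sorted({g for s in config.genes_per_taxon.values() for g in s})
    if all_genes:
        for name in names:
            if not config.genes_per_taxon.get(name):
                warnings.warn(
                    f"taxon {name!r} has an empty gene set; it contributes "
                    "only to the taxon-level table",
                    stacklevel=2,
                )
        incidence = np.zeros((len(all_genes), config.n_taxa))
        gene_pos = {g: i for i, g in enumerate(all_genes)}
        for j, name in enumerate(names):
            for g in config.genes_per_taxon.get(name, ()):
                incidence[gene_pos[g], j] = 1.0
        gene_data = pd.DataFrame(
            incidence @ counts, index=all_genes, columns=cols
        )
        systems = pd.Series([_system_of(g) for g in all_genes], index=all_genes)
        for system in systems.unique():
            idx = systems[systems == system].index
            meta = pd.DataFrame(
                {"system": system, "lineage": ""}, index=idx
            )
            tables[system] = CoverageTable(gene_data.loc[idx], meta)

    # injected anomaly truth
    months = np.arange(1, 13)
    truth_month = pd.DataFrame(
        _seasonal(
            months[None, :],
            config.seasonal_amplitude[:, None],
            config.seasonal_peak_month[:, None],
        ),
        index=names,
        columns=months,
    )
    years = np.unique(dates.year.to_numpy())
    enso_y = config.enso_at(years)
    truth_year = pd.DataFrame(
        config.enso_sensitivity[:, None] * (enso_y - enso_y.mean())[None, :],
        index=names,
        columns=years,
    )
    if all_genes:
        w = rel_df.mean(axis=1).to_numpy()
        carrier_w = incidence * w[None, :]
        denom = carrier_w.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        gene_month = (carrier_w / denom) @ truth_month.to_numpy()
        gene_truth_month = pd.DataFrame(gene_month, index=all_genes, columns=months)
    else:
        gene_truth_month = pd.DataFrame(columns=months)

    ags = pd.Series(
        (rel * config.genome_size[:, None]).sum(axis=0), index=cols, name="ags"
    )
    truth = SyntheticTruth(
        latent=latent_df,
        rel_abundance=rel_df,
        counts=counts_df,
        monthly_effects=truth_month,
        yearly_effects=truth_year,
        gene_monthly_effects=gene_truth_month,
        ags=ags,
        genome_size=pd.Series(config.genome_size, index=names),
    )
    return tables, truth


def simulate_contigs(
    config: SimulationConfig,
    n_contigs: int = 500,
    orfs_per_contig: int = 10,
    misassignment_rate: float = 0.0,
) -> tuple[list, pd.Series]:
    """Simulate contigs with per-ORF lineages for consensus-taxonomy tests.

    Each contig originates from one source taxon (drawn by mean relative
    abundance); every ORF carries the source lineage with probability
    1 - misassignment_rate, else the lineage of a random other taxon.  ORFs
    also carry functional IDs sampled from the source taxon's gene set.

    Returns the contigs and a Series mapping contig_id -> source taxon.
    """
    if not 0 <= misassignment_rate < 0.5:
        raise ValueError("misassignment_rate must be in [0, 0.5)")
    rng = np.random.default_rng([config.seed, 3])
    paths = [TaxonomyPath.from_string(s) for s in config.lineages]
    det = _latent(
        SimulationConfig(
            **{
                **config.__dict__,
                "noise_sd": 0.0,
            }
        ),
        rng,
    )
    weights = _softmax(det).mean(axis=1)
    sources = rng.choice(config.n_taxa, size=n_contigs, p=weights)
    contigs, truth = [], {}
    for c, src in enumerate(sources):
        cid = f"contig_{c:05d}"
        coverage = float(
            weights[src] * 100.0 * rng.lognormal(mean=0.0, sigma=0.3)
        )
        lineages, functions = [], []
        gene_pool = sorted(config.genes_per_taxon.get(config.taxon_names[src], ()))
        for _ in range(orfs_per_contig):
            if misassignment_rate > 0 and rng.random() < misassignment_rate:
                other = int(rng.integers(config.n_taxa - 1))
                if other >= src:
                    other += 1
                lineages.append(paths[other])
            else:
                lineages.append(paths[src])
            if gene_pool and rng.random() < 0.7:
                functions.append({gene_pool[rng.integers(len(gene_pool))]})
            else:
                functions.append(set())
        contigs.append(ContigRecord(cid, coverage, lineages, functions))
        truth[cid] = config.taxon_names[src]
    return contigs, pd.Series(truth, name="source_taxon")


def simulate_marker_counts(
    config: SimulationConfig,
    taxon_counts: pd.DataFrame | None = None,
    marker_ids=SINGLE_COPY_MARKERS,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-sample single-copy marker coverage and assembled-base totals.

    Every taxon carries each marker exactly once, so each marker's coverage
    equals the total cell coverage of the sample (optionally perturbed by
    multiplicative noise with CV ``config.marker_noise_cv``); total assembled
    bases are the genome-size-weighted sum of taxon coverage.

    Returns (markers x samples coverage table, per-sample total bases,
    per-sample true abundance-weighted mean genome size).
    """
    if taxon_counts is None:
        _, truth = simulate_community(config)
        taxon_counts = truth.counts
    rng = np.random.default_rng([config.seed, 4])
    total_cov = taxon_counts.sum(axis=0).to_numpy(dtype=float)
    base = np.tile(total_cov, (len(marker_ids), 1))
    if config.marker_noise_cv > 0:
        base = base * rng.lognormal(
            mean=-0.5 * np.log1p(config.marker_noise_cv**2),
            sigma=np.sqrt(np.log1p(config.marker_noise_cv**2)),
            size=base.shape,
        )
    markers = pd.DataFrame(base, index=list(marker_ids), columns=taxon_counts.columns)
    genome = config.genome_size[:, None]
    total_bases = pd.Series(
        (taxon_counts.to_numpy() * genome).sum(axis=0),
        index=taxon_counts.columns,
        name="total_bases",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        true_ags = total_bases / taxon_counts.sum(axis=0)
    true_ags.name = "true_ags"
    return markers, total_bases, true_ags
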