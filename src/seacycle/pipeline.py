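"""End-to-end pipeline: normalize -> anomaly -> ordination -> traits ->
keywords -> average genome size, with provenance for every output."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import genome_size as gs
from .anomaly import SeasonalAnomalyModel
from .containers import CoverageTable
from .io import provenance_header, read_coverage_table, write_provenance
from .normalize import DEFAULT_MIN_ABUNDANCE, filter_rare, to_proportions, zscore
from .ordination import MCOA, Permanova, pca
from .traits import aggregate_trait, load_trait_definitions, trait_anomalies

log = logging.getLogger("seacycle")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    coverage_tables: dict  # system name -> TSV path
    output_dir: str
    trait_definitions: str | None = None
    marker_table: str | None = None  # markers x samples TSV
    total_bases: str | None = None  # per-sample total assembled bases TSV
    annotations: str | None = None  # gene_id, system, description TSV
    min_abundance: float = DEFAULT_MIN_ABUNDANCE
    systems_for_mcoa: list = field(default_factory=list)
    n_perm: int = 999
    mcoa_table_scaling: str = "inertia"
    seed: int = 42

    def validate(self) -> None:
        for name, path in self.coverage_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"coverage table {name!r}: {path}")
        for attr in ("trait_definitions", "marker_table", "total_bases", "annotations"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path}")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write_tsv(frame: pd.DataFrame, path: Path, stage: str, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, **params) + "\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    The run is deterministic under a fixed seed: two runs with the same
    configuration produce byte-identical numeric outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {
        name: read_coverage_table(path)
        for name, path in config.coverage_tables.items()
    }

    # normalize + anomaly per system
    ztables = {}
    for name, table in tables.items():
        log.info("normalizing %s", name)
        props = filter_rare(to_proportions(table), config.min_abundance)
        z = zscore(props)
        ztables[name] = z
        with open(outdir / f"dropped_features_{name}.json", "w") as fh:
            json.dump(
                {
                    "below_threshold": props.dropped_features,
                    "zero_variance": z.dropped_constant,
                },
                fh,
                indent=2,
            )
        log.info("fitting anomalies for %s (%d features)", name, len(z.data))
        fits = SeasonalAnomalyModel(z.data, z.dates).fit()
        _write_tsv(
            fits.frame(), outdir / f"anomaly_{name}.tsv", "anomaly",
            system=name, min_abundance=config.min_abundance, seed=config.seed,
        )

        res = pca(z, mode="samples")
        _write_tsv(
            res.scores, outdir / f"pca_samples_{name}.tsv", "pca",
            system=name, mode="samples", seed=config.seed,
        )

        factors = pd.DataFrame(
            {"month": z.dates.month, "year": z.dates.year}
        )
        perma = Permanova(z, factors, interaction=True).fit(
            n_perm=config.n_perm, seed=config.seed
        )
        perma.table.reset_index().to_json(
            outdir / f"permanova_{name}.json", orient="records", indent=2
        )

    # MCOA across systems
    mcoa_systems = config.systems_for_mcoa or list(ztables)
    if len(mcoa_systems) >= 2:
        log.info("MCOA across %s", mcoa_systems)
        res = MCOA(
            {k: ztables[k] for k in mcoa_systems},
            table_scaling=config.mcoa_table_scaling,
        ).fit(n_axes=2)
        _write_tsv(
            res.scores, outdir / "mcoa_scores.tsv", "mcoa",
            systems=",".join(mcoa_systems), seed=config.seed,
        )
        with open(outdir / "mcoa_eigenvalues.json", "w") as fh:
            json.dump(
                {
                    "pseudo_eigenvalues": list(map(float, res.eigenvalues)),
                    "variance_fractions": list(map(float, res.variance_fractions)),
                },
                fh,
                indent=2,
            )

    # traits
    if config.trait_definitions:
        defs = load_trait_definitions(config.trait_definitions)
        rows = {}
        for name, defn in defs.items():
            source = next(
                (t for t in tables.values()
                 if any(g in t.data.index for g in defn.gene_ids)),
                None,
            )
            if source is None:
                log.warning("trait %s: no member genes in any table", name)
                continue
            ts = aggregate_trait(source, defn)
            fit = trait_anomalies(ts)
            rows[name] = {
                "mean_proportion": float(ts.proportions.mean()),
                "peak_month": fit.peak_month,
                "peak_year": fit.peak_year,
                **{f"month_{m}": v for m, v in fit.scaled_monthly.items()},
                **{f"year_{y}": v for y, v in fit.scaled_yearly.items()},
            }
        _write_tsv(
            pd.DataFrame.from_dict(rows, orient="index"),
            outdir / "traits.tsv", "traits", seed=config.seed,
        )

    # keywords
    if config.annotations:
        from .keywords import extract_keywords, keyword_series, rank_keywords

        ann = pd.read_csv(config.annotations, sep="\t", comment="#")
        mapping = dict(zip(ann["gene_id"], ann["description"].fillna("")))
        gene_system = next((n for n in ztables if n != "family"), None)
        if gene_system is not None:
            props = filter_rare(
                to_proportions(tables[gene_system]), config.min_abundance
            )
            kseries = keyword_series(extract_keywords(mapping), props)
            if kseries:
                seasonal, annual = rank_keywords(kseries, top_n=50)
                _write_tsv(seasonal, outdir / "keywords_seasonal.tsv",
                           "keywords", seed=config.seed)
                _write_tsv(annual, outdir / "keywords_annual.tsv",
                           "keywords", seed=config.seed)

    # average genome size
    if config.marker_table and config.total_bases:
        markers = pd.read_csv(
            config.marker_table, sep="\t", comment="#", index_col=0
        )
        bases = pd.read_csv(
            config.total_bases, sep="\t", comment="#", index_col=0
        ).iloc[:, 0]
        frame, fit = gs.ags_series(markers, bases)
        _write_tsv(frame, outdir / "ags.tsv", "ags", seed=config.seed)

    write_provenance(
        outdir / "provenance.json", "run_pipeline",
        seed=config.seed, min_abundance=config.min_abundance,
        n_perm=config.n_perm, tables=list(config.coverage_tables),
    )
    return outdir
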