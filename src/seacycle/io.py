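"""Readers and writers for the pipeline's table dialects.

Canonical dialect: UTF-8 TSV, "." decimal, scientific notation accepted on
read, 10 significant digits on write.  Coverage tables carry the feature
metadata columns (feature_id, system, lineage) before the sample columns;
every file written by a pipeline stage starts with '#'-prefixed provenance
header lines sufficient to re-run the stage.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone

import pandas as pd

from . import __version__
from .containers import CoverageTable
from .taxonomy import ContigRecord, TaxonomyPath

__all__ = [
    "read_coverage_table",
    "write_coverage_table",
    "read_contigs",
    "write_contigs",
    "provenance_header",
    "write_provenance",
]

_FLOAT_FMT = "%.10g"
META_COLUMNS = ("feature_id", "system", "lineage")


def provenance_header(stage: str, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return f"# seacycle {__version__} | stage={stage} | {items} | written={stamp}"


def write_coverage_table(table: CoverageTable, path, stage="coverage", **params) -> None:
    frame = table.meta.copy()
    frame.insert(0, "feature_id", table.data.index)
    out = pd.concat([frame.reset_index(drop=True),
                     table.data.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, **params) + "\n")
        out.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_coverage_table(path) -> CoverageTable:
    """Read a coverage TSV; raises a located error on malformed cells."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    sample_cols = [c for c in frame.columns if c not in META_COLUMNS]
    data = {}
    for col in sample_cols:
        try:
            data[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(
                f"{path}: malformed numeric value at row {row}, column {col!r}"
            ) from None
        if data[col].isna().any():
            row = int(data[col].index[data[col].isna()][0])
            raise ValueError(
                f"{path}: missing value at row {row}, column {col!r}"
            )
    matrix = pd.DataFrame(data)
    matrix.index = pd.Index(frame["feature_id"].to_numpy())
    meta = frame[["system", "lineage"]].fillna("")
    meta.index = matrix.index
    return CoverageTable(matrix, meta)


def write_contigs(contigs, path, stage="contigs", **params) -> None:
    """Contig TSV: one row per ORF (contig_id, coverage, orf_id,
    lineage_string, ko, pfam, cog, tigrfam)."""
    rows = []
    for contig in contigs:
        for i, (lin, funcs) in enumerate(
            zip(contig.orf_lineages, contig.orf_functions)
        ):
            by_sys = {"ko": [], "pfam": [], "cog": [], "tigrfam": []}
            for gid in sorted(funcs):
                if gid.startswith("K"):
                    by_sys["ko"].append(gid)
                elif gid.startswith("PF"):
                    by_sys["pfam"].append(gid)
                elif gid.startswith("COG"):
                    by_sys["cog"].append(gid)
                elif gid.startswith("TIGR"):
                    by_sys["tigrfam"].append(gid)
            rows.append(
                {
                    "contig_id": contig.contig_id,
                    "coverage": contig.coverage,
                    "orf_id": f"{contig.contig_id}_orf{i:03d}",
                    "lineage_string": lin.to_string(),
                    **{k: ",".join(v) for k, v in by_sys.items()},
                }
            )
    frame = pd.DataFrame.from_records(rows)
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, **params) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_contigs(path) -> list:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    contigs = []
    for cid, group in frame.groupby("contig_id", sort=False):
        lineages = [TaxonomyPath.from_string(s) for s in group["lineage_string"]]
        functions = []
        for _, row in group.iterrows():
            ids = set()
            for col in ("ko", "pfam", "cog", "tigrfam"):
                val = row.get(col)
                if isinstance(val, str) and val:
                    ids |= set(val.split(","))
            functions.append(ids)
        contigs.append(
            ContigRecord(
                contig_id=cid,
                coverage=float(group["coverage"].iloc[0]),
                orf_lineages=lineages,
                orf_functions=functions,
            )
        )
    return contigs


def write_provenance(path, stage: str, **params) -> None:
    payload = {
        "tool": "seacycle",
        "version": __version__,
        "stage": stage,
        "written": datetime.now(timezone.utc).isoformat(),
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _jsonable(v):
    try:
        json.dumps(v)
        return v
    except TypeError:
        return str(v)
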