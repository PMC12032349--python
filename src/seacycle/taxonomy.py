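"""Consensus contig taxonomy and taxonomic aggregation.

Assembled contigs carry multiple open reading frames (ORFs), each with its
own best-hit lineage; the contig's taxonomy is resolved by a majority rule:
the lineage at the lowest (deepest) taxonomic rank to which at least half of
the contig's ORFs are assigned.  Contig coverage then aggregates to
family-level abundance tables, and gene families are attributed to phyla by
the consensus phylogeny of the contigs that carry them, weighted by contig
coverage.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CoverageTable

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "TaxonomyPath",
    "ContigRecord",
    "consensus_lineage",
    "family_table",
    "gene_family_phylum_profile",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered seven-rank lineage (domain..species).

    Ranks unassigned are "unclassified"; once a rank is unclassified every
    lower rank is too (enforced at construction).
    """

    names: tuple

    def __init__(self, names):
        names = list(names)
        if len(names) > len(RANKS):
            raise ValueError(f"at most {len(RANKS)} ranks, got {len(names)}")
        names += [UNCLASSIFIED] * (len(RANKS) - len(names))
        # enforce the prefix property
        seen_unclassified = False
        cleaned = []
        for name in names:
            if not name or name == UNCLASSIFIED or seen_unclassified:
                seen_unclassified = True
                cleaned.append(UNCLASSIFIED)
            else:
                cleaned.append(str(name))
        object.__setattr__(self, "names", tuple(cleaned))

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonomyPath":
        """Parse a semicolon-delimited GTDB-style string
        ("d__Bacteria;p__Proteobacteria;...")."""
        names = []
        for part in str(lineage).split(";"):
            part = part.strip()
            if not part:
                continue
            for pref in RANK_PREFIXES:
                if part.startswith(pref):
                    part = part[len(pref):]
                    break
            names.append(part if part else UNCLASSIFIED)
        return cls(names)

    def to_string(self) -> str:
        return ";".join(
            f"{p}{'' if n == UNCLASSIFIED else n}"
            for p, n in zip(RANK_PREFIXES, self.names)
        )

    def at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        """Number of classified ranks."""
        for i, n in enumerate(self.names):
            if n == UNCLASSIFIED:
                return i
        return len(RANKS)

    @property
    def deepest_rank(self) -> str | None:
        d = self.depth
        return RANKS[d - 1] if d else None

    def __iter__(self):
        return iter(self.names)


@dataclass
class ContigRecord:
    """One assembled contig: its coverage, its ORFs' lineages and the
    functional IDs (KO/COG/Pfam/TIGRfam) annotated on each ORF."""

    contig_id: str
    coverage: float
    orf_lineages: list
    orf_functions: list = field(default_factory=list)

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not self.orf_lineages:
            raise ValueError("a contig needs at least one ORF")
        if not self.orf_functions:
            self.orf_functions = [set() for _ in self.orf_lineages]

    @property
    def gene_ids(self) -> set:
        out = set()
        for ids in self.orf_functions:
            out |= set(ids)
        return out


def consensus_lineage(
    contig: ContigRecord, threshold: float = 0.5
) -> tuple[TaxonomyPath, bool]:
    """Majority-rule consensus: the lineage at the lowest rank to which at
    least ``threshold`` of the contig's ORFs is assigned.

    Evaluation proceeds domain -> species and stops at the first rank where
    no taxon reaches the threshold; ORFs unclassified at a rank still count
    in the denominator.  When two taxa both reach the threshold at a rank
    (possible only at exactly 50% with the default), the taxon whose
    supporting ORFs best agree with the consensus at the parent rank wins;
    remaining ties break lexicographically.

    Returns
    -------
    (path, classified) : the consensus path and a flag that is False when no
    ORF was classifiable even at domain rank.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    total = len(contig.orf_lineages)
    chosen: list[str] = []
    for depth, rank in enumerate(RANKS):
        counts = Counter(
            lin.names[depth]
            for lin in contig.orf_lineages
            if lin.names[depth] != UNCLASSIFIED
        )
        passing = [t for t, c in counts.items() if c / total >= threshold]
        if not passing:
            break
        if len(passing) == 1:
            chosen.append(passing[0])
            continue
        # tie-break: parent consistency first, then support, then name
        def parent_support(taxon: str) -> int:
            if not chosen:
                return 0
            return sum(
                1
                for lin in contig.orf_lineages
                if lin.names[depth] == taxon and lin.names[depth - 1] == chosen[-1]
            )

        chosen.append(
            min(passing, key=lambda t: (-parent_support(t), -counts[t], t))
        )
    return TaxonomyPath(chosen), bool(chosen)


def family_table(
    contigs,
    sample_coverages: pd.DataFrame,
    threshold: float = 0.5,
) -> CoverageTable:
    """Aggregate per-contig, per-sample coverage to family-level features.

    Contigs whose consensus reaches family rank contribute to that family;
    contigs resolved only to a shallower rank accumulate under
    ``"<rank>:<name>_unresolved"`` and fully unclassified contigs under
    ``"unclassified"``, so the table's column sums conserve total contig
    coverage.

    Parameters
    ----------
    contigs : iterable of ContigRecord
    sample_coverages : DataFrame
        Contig IDs x sample IDs coverage matrix.
    """
    contigs = list(contigs)
    rows: dict[str, np.ndarray] = {}
    lineages: dict[str, str] = {}
    fam_idx = RANKS.index("family")
    for contig in contigs:
        path, classified = consensus_lineage(contig, threshold)
        if not classified:
            label, lineage = UNCLASSIFIED, ""
        elif path.depth > fam_idx:
            label = path.at("family")
            lineage = path.to_string()
        else:
            rank = path.deepest_rank
            label = f"{rank}:{path.at(rank)}_unresolved"
            lineage = path.to_string()
        cov = sample_coverages.loc[contig.contig_id].to_numpy(dtype=float)
        if label in rows:
            rows[label] = rows[label] + cov
        else:
            rows[label] = cov.copy()
            lineages[label] = lineage
    data = pd.DataFrame.from_dict(
        rows, orient="index", columns=sample_coverages.columns
    )
    meta = pd.DataFrame(
        {"system": "family", "lineage": pd.Series(lineages)}, index=data.index
    )
    return CoverageTable(data, meta)


def gene_family_phylum_profile(
    contigs, gene_id: str, threshold: float = 0.5
) -> pd.Series:
    """Phylum-level attribution of one gene family.

    Sums the coverage of every contig carrying ``gene_id`` into its consensus
    phylum, then normalizes to the across-phylum total, giving the fraction
    of the gene family's coverage contributed by each phylum.
    """
    sums: dict[str, float] = defaultdict(float)
    found = False
    for contig in contigs:
        if gene_id not in contig.gene_ids:
            continue
        found = True
        path, classified = consensus_lineage(contig, threshold)
        phylum = path.at("phylum") if classified else UNCLASSIFIED
        sums[phylum] += contig.coverage
    if not found:
        warnings.warn(f"gene {gene_id!r} absent from all contigs", stacklevel=2)
        return pd.Series(dtype=float, name=gene_id)
    profile = pd.Series(sums, name=gene_id).sort_values(ascending=False)
    return profile / profile.sum()
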