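"""Bin quality filtering, species aggregation, and extraction of the
marker-gene (Ni-dependent enzyme) community.

Bins are CheckM-style records (completeness, contamination, strain
heterogeneity as percentages).  Quality filtering keeps bins with
completeness > 60%, contamination < 10% and strain heterogeneity < 10%
(strict inequalities).  Bins with the same species label are summed into a
SpeciesAggregate; the marker community is the subset of aggregates owning
at least one scaffold that carries a retained marker hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import DiffResult
from .markers import MarkerHit

__all__ = [
    "BinRecord",
    "SpeciesAggregate",
    "filter_bins",
    "aggregate_species",
    "extract_marker_community",
    "partition_populations",
    "marker_coverage_fraction",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class BinRecord:
    """A genome bin: scaffold membership plus CheckM-style quality metrics."""

    bin_id: str
    scaffolds: tuple[str, ...]
    completeness: float
    contamination: float
    strain_heterogeneity: float
    species: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise ValueError(f"bin {self.bin_id} has no scaffolds")
        for name, v in (
            ("completeness", self.completeness),
            ("contamination", self.contamination),
            ("strain_heterogeneity", self.strain_heterogeneity),
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"bin {self.bin_id}: {name}={v} outside [0, 100]")


def bins_from_frame(df: pd.DataFrame) -> list[BinRecord]:
    """Build BinRecords from a bin-table DataFrame (see io.read_bin_table)."""
    if df["bin_id"].duplicated().any():
        raise ValueError("duplicate bin_id in bin table")
    return [
        BinRecord(
            r.bin_id,
            tuple(r.scaffold_ids),
            float(r.completeness),
            float(r.contamination),
            float(r.strain_heterogeneity),
            str(r.species),
        )
        for r in df.itertuples()
    ]


def filter_bins(
    bins: Sequence[BinRecord],
    min_completeness: float = 60.0,
    max_contamination: float = 10.0,
    max_heterogeneity: float = 10.0,
) -> list[BinRecord]:
    """Keep bins passing the quality gate (strict inequalities), in order."""
    for name, v in (
        ("min_completeness", min_completeness),
        ("max_contamination", max_contamination),
        ("max_heterogeneity", max_heterogeneity),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return [
        b
        for b in bins
        if b.completeness > min_completeness
        and b.contamination < max_contamination
        and b.strain_heterogeneity < max_heterogeneity
    ]


@dataclass
class SpeciesAggregate:
    """Species-level union of same-labelled bins.

    KO set is the union over member scaffolds' genes; abundance is the
    per-sample sum over member scaffolds; average completeness is the
    arithmetic mean of member-bin completeness (percent).
    """

    species: str
    bin_ids: tuple[str, ...]
    scaffolds: tuple[str, ...]
    ko_set: frozenset[str]
    abundance: pd.Series
    avg_completeness: float
    enzymes: frozenset[str] = field(default_factory=frozenset)


def aggregate_species(
    bins: Sequence[BinRecord],
    scaffold_genes: Mapping[str, Sequence[str]],
    ko_map: Mapping[str, str],
    scaffold_abundance: pd.DataFrame,
) -> list[SpeciesAggregate]:
    """Sum QC-passed bins with the same species label into aggregates.

    Bins labelled "unclassified" survive QC but are excluded here.  A
    scaffold claimed by bins of two different species is an error; within a
    species a scaffold is counted once.
    """
    owner: dict[str, str] = {}
    for b in bins:
        for sc in b.scaffolds:
            prev = owner.setdefault(sc, b.species)
            if prev != b.species:
                raise ValueError(
                    f"scaffold {sc} claimed by bins of species "
                    f"'{prev}' and '{b.species}'"
                )
    aggregates = []
    by_species: dict[str, list[BinRecord]] = {}
    for b in bins:
        if b.species == UNCLASSIFIED:
            continue
        by_species.setdefault(b.species, []).append(b)
    for species, members in by_species.items():
        scaffolds = tuple(dict.fromkeys(sc for b in members for sc in b.scaffolds))
        missing = [sc for sc in scaffolds if sc not in scaffold_abundance.index]
        if missing:
            raise ValueError(f"scaffold(s) without abundance: {missing}")
        genes = [g for sc in scaffolds for g in scaffold_genes.get(sc, ())]
        kos = frozenset(ko_map[g] for g in genes if g in ko_map)
        abundance = scaffold_abundance.loc[list(scaffolds)].sum(axis=0)
        avg_comp = float(np.mean([b.completeness for b in members]))
        aggregates.append(
            SpeciesAggregate(
                species,
                tuple(b.bin_id for b in members),
                scaffolds,
                kos,
                abundance,
                avg_comp,
            )
        )
    return aggregates


def extract_marker_community(
    aggregates: Sequence[SpeciesAggregate],
    hits: Sequence[MarkerHit],
    gene_scaffold: Mapping[str, str],
) -> list[SpeciesAggregate]:
    """Keep aggregates owning >=1 scaffold carrying a marker hit, annotated
    with the enzyme complement found on their scaffolds."""
    unresolved = [h.gene_id for h in hits if h.gene_id not in gene_scaffold]
    if unresolved:
        raise ValueError(f"marker hit gene(s) without a scaffold: {unresolved}")
    by_scaffold: dict[str, set[str]] = {}
    for h in hits:
        by_scaffold.setdefault(gene_scaffold[h.gene_id], set()).add(h.enzyme)
    community = []
    for agg in aggregates:
        enzymes = frozenset(
            e for sc in agg.scaffolds for e in by_scaffold.get(sc, ())
        )
        if enzymes:
            community.append(
                SpeciesAggregate(
                    agg.species,
                    agg.bin_ids,
                    agg.scaffolds,
                    agg.ko_set,
                    agg.abundance,
                    agg.avg_completeness,
                    enzymes,
                )
            )
    return community


def partition_populations(
    community: Sequence[SpeciesAggregate],
    diff: DiffResult,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign each community species to the upregulated / downregulated /
    unchanged population from its species-level differential result.

    Upregulated: q < alpha and treatment mean > reference mean;
    downregulated: q < alpha and treatment mean < reference mean.
    """
    table = diff.table
    missing = [a.species for a in community if a.species not in table.index]
    if missing:
        raise ValueError(f"species without a differential result: {missing}")
    label_map = {
        "increased": "upregulated",
        "decreased": "downregulated",
        "unchanged": "unchanged",
    }
    out = {}
    for agg in community:
        row = table.loc[agg.species]
        if row["q"] < alpha and row["direction"] != "unchanged":
            out[agg.species] = label_map[row["direction"]]
        else:
            out[agg.species] = "unchanged"
    return out


def marker_coverage_fraction(
    hits: Sequence[MarkerHit],
    qc_bins: Sequence[BinRecord],
    gene_abundance: pd.DataFrame,
    gene_scaffold: Mapping[str, str],
    enzyme: str,
) -> tuple[pd.Series, tuple[float, float]]:
    """Fraction of an enzyme's total marker abundance captured by QC bins.

    Per sample: summed TPM of the enzyme's hit genes located on QC-bin
    scaffolds divided by the summed TPM of all that enzyme's hit genes.
    Returns the per-sample fractions and their (min, max) range; samples
    with zero total marker abundance are excluded from the range with a
    warning.
    """
    enzyme_hits = [h for h in hits if h.enzyme == enzyme]
    if not enzyme_hits:
        raise ValueError(f"no marker hits for enzyme '{enzyme}'")
    binned = {sc for b in qc_bins for sc in b.scaffolds}
    all_genes = [h.gene_id for h in enzyme_hits]
    in_genes = [g for g in all_genes if gene_scaffold.get(g) in binned]
    total = gene_abundance.loc[all_genes].sum(axis=0)
    inside = (
        gene_abundance.loc[in_genes].sum(axis=0)
        if in_genes
        else pd.Series(0.0, index=gene_abundance.columns)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = inside / total
    undefined = total == 0
    if undefined.any():
        warnings.warn(
            f"zero total {enzyme} abundance in sample(s) "
            f"{total.index[undefined].tolist()}; excluded from range"
        )
        frac[undefined] = np.nan
    valid = frac.dropna()
    if valid.empty:
        raise ValueError(f"coverage fraction undefined in every sample for {enzyme}")
    return frac, (float(valid.min()), float(valid.max()))


def community_table(
    community: Sequence[SpeciesAggregate],
    diff: DiffResult,
    populations: Mapping[str, str],
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Species × (enzymes, group mean ± SEM, q, population) summary table.

    SEM columns are included when the sample→group mapping is given.
    """
    from scipy.stats import sem

    ref, treat = diff.reference, diff.treatment
    rows = []
    for agg in community:
        row = diff.table.loc[agg.species]
        entry = {
            "species": agg.species,
            "enzymes": ",".join(sorted(agg.enzymes)),
            f"mean_{ref}": row[f"mean_{ref}"],
            f"mean_{treat}": row[f"mean_{treat}"],
            "q": row["q"],
            "population": populations[agg.species],
        }
        if groups is not None:
            for grp in (ref, treat):
                vals = agg.abundance[groups.index[groups == grp]]
                entry[f"sem_{grp}"] = float(sem(vals))
        rows.append(entry)
    df = pd.DataFrame(rows)
    if groups is not None:
        order = ["species", "enzymes", f"mean_{ref}", f"sem_{ref}",
                 f"mean_{treat}", f"sem_{treat}", "q", "population"]
        df = df[order]
    return df
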