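"""Pathway definitions, the completeness-normalized pathway statistic,
population comparisons, and hypergeometric pathway enrichment.

A pathway is an ordered list of sub-pathways; each sub-pathway is a list of
pathway enzyme genes (PEGs); each PEG is one enzymatic step represented by
a set of interchangeable KO ids.  A PEG counts as *detected* in a species
when at least one of its KOs occurs in the species' aggregated gene set.

The pathway-completeness statistic normalizes the detected PEG count by
genome recovery: ``detected PEGs / average bin completeness`` (completeness
as a fraction in (0, 1]), so partially recovered genomes are not penalized
for missing enzymes their bins simply failed to capture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import DiffResult, bh_fdr

__all__ = [
    "PEG",
    "SubPathway",
    "PathwayDef",
    "load_pathway_definitions",
    "default_pathway_definitions",
    "detect_pegs",
    "pathway_completeness",
    "completeness_table",
    "compare_populations",
    "enrich_pathway",
    "enrich_all",
    "EnrichmentResult",
]

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class PEG:
    """One enzymatic step: an integer code and interchangeable KO ids."""

    code: int
    kos: frozenset[str]


@dataclass(frozen=True)
class SubPathway:
    name: str
    pegs: tuple[PEG, ...]

    @property
    def kos(self) -> frozenset[str]:
        return frozenset(ko for peg in self.pegs for ko in peg.kos)


@dataclass(frozen=True)
class PathwayDef:
    id: str
    name: str
    subpathways: tuple[SubPathway, ...]

    @property
    def kos(self) -> frozenset[str]:
        return frozenset(ko for sp in self.subpathways for ko in sp.kos)


def _parse_pathway(entry: dict, where: str) -> PathwayDef:
    subpathways = []
    seen_names: set[str] = set()
    code_kos: dict[int, frozenset[str]] = {}
    for sp in entry.get("subpathways", []):
        name = sp.get("name")
        if not name:
            raise ValueError(f"{where}: sub-pathway without a name")
        if name in seen_names:
            raise ValueError(f"{where}: duplicate sub-pathway name '{name}'")
        seen_names.add(name)
        pegs = []
        for peg in sp.get("pegs", []):
            code = peg.get("code")
            kos = peg.get("kos", [])
            loc = f"{where}, sub-pathway '{name}', PEG {code}"
            if not isinstance(code, int):
                raise ValueError(f"{loc}: PEG code must be an integer")
            if not kos:
                raise ValueError(f"{loc}: PEG has no KO ids")
            for ko in kos:
                if not _KO_RE.match(str(ko)):
                    raise ValueError(f"{loc}: malformed KO id '{ko}'")
            koset = frozenset(kos)
            # shared steps (same code in two sub-pathways) must agree on KOs
            if code in code_kos and code_kos[code] != koset:
                raise ValueError(
                    f"{loc}: PEG code {code} re-used with a different KO set"
                )
            code_kos[code] = koset
            pegs.append(PEG(code, koset))
        subpathways.append(SubPathway(name, tuple(pegs)))
    if not subpathways:
        raise ValueError(f"{where}: pathway has no sub-pathways")
    return PathwayDef(entry["id"], entry.get("name", entry["id"]), tuple(subpathways))


def load_pathway_definitions(path: str | Path) -> list[PathwayDef]:
    """Parse pathway definitions from a YAML file (schema: pathways →
    subpathways → pegs → kos)."""
    from . import io as nio

    data = nio.load_yaml(path)
    if "pathways" not in data or not data["pathways"]:
        raise ValueError(f"{path}: no 'pathways' section")
    defs = []
    for i, entry in enumerate(data["pathways"]):
        if "id" not in entry:
            raise ValueError(f"{path}: pathway #{i} has no id")
        defs.append(_parse_pathway(entry, f"{path}: pathway '{entry['id']}'"))
    return defs


def default_pathway_definitions() -> list[PathwayDef]:
    """The bundled SCFA-generation reconstruction (10 sub-pathways) plus the
    auxiliary fatty-acid / nitrogen / sulfur pathways."""
    ref = resources.files("nicomm.data") / "scfa_pathways.yaml"
    with resources.as_file(ref) as path:
        return load_pathway_definitions(path)


def detect_pegs(species_kos: Iterable[str], pegs: Sequence[PEG]) -> int:
    """Count the PEGs with at least one KO present in the species' KO set."""
    kos = set(species_kos)
    return sum(1 for peg in pegs if not kos.isdisjoint(peg.kos))


def detect_kos(species_kos: Iterable[str], pegs: Sequence[PEG]) -> int:
    """Count the distinct pathway KOs present in the species' KO set (the
    alternative counting unit to whole PEGs)."""
    kos = set(species_kos)
    return len(kos & {ko for peg in pegs for ko in peg.kos})


def pathway_completeness(detected_pegs: int, avg_completeness: float) -> float:
    """Detected PEG count normalized by average bin completeness (fraction)."""
    if not 0.0 < avg_completeness <= 1.0:
        raise ValueError(
            f"avg_completeness must be in (0, 1], got {avg_completeness}"
        )
    return detected_pegs / avg_completeness


def completeness_table(
    species_kos: Mapping[str, Iterable[str]],
    species_completeness: Mapping[str, float],
    definitions: Sequence[PathwayDef],
    count: str = "peg",
) -> pd.DataFrame:
    """Per-(species, sub-pathway) completeness statistics.

    ``species_completeness`` holds average bin completeness as fractions.
    ``count`` selects the counting unit: whole PEGs (default) or member
    KOs.  Returns a long table: species, pathway, subpathway,
    detected_pegs, avg_completeness, statistic.
    """
    if count not in ("peg", "ko"):
        raise ValueError(f"count must be 'peg' or 'ko', got '{count}'")
    counter = detect_pegs if count == "peg" else detect_kos
    rows = []
    for species, kos in species_kos.items():
        comp = species_completeness[species]
        for pdef in definitions:
            for sp in pdef.subpathways:
                n = counter(kos, sp.pegs)
                rows.append(
                    (species, pdef.name, sp.name, n, comp,
                     pathway_completeness(n, comp))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "pathway", "subpathway",
            "detected_pegs", "avg_completeness", "statistic",
        ],
    )


def _anova(groups: list[np.ndarray]) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # identical values everywhere
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def compare_populations(
    records: pd.DataFrame,
    populations: Mapping[str, str],
    min_group_size: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA of the completeness statistic across populations.

    ``records`` is a ``completeness_table`` output; ``populations`` maps
    species → population label (e.g. upregulated / downregulated /
    unchanged).  Sub-pathways where any population has fewer than
    ``min_group_size`` species are flagged untestable and excluded from the
    BH adjustment.  Returns one row per sub-pathway with F, p, q and
    per-population mean ± SEM.
    """
    missing = sorted(set(records["species"]) - set(populations))
    if missing:
        raise ValueError(f"species without a population label: {missing}")
    labels = sorted(set(populations.values()))
    rows = []
    for (pathway, subpathway), sub in records.groupby(
        ["pathway", "subpathway"], sort=False
    ):
        by_label = {
            lab: sub.loc[
                sub["species"].map(populations) == lab, "statistic"
            ].to_numpy(float)
            for lab in labels
        }
        testable = all(len(v) >= min_group_size for v in by_label.values()) and len(
            by_label
        ) >= 2
        row: dict = {"pathway": pathway, "subpathway": subpathway, "testable": testable}
        for lab, vals in by_label.items():
            row[f"mean_{lab}"] = vals.mean() if len(vals) else np.nan
            row[f"sem_{lab}"] = (
                stats.sem(vals) if len(vals) > 1 else np.nan
            )
        if testable:
            row["F"], row["p"] = _anova(list(by_label.values()))
        else:
            row["F"], row["p"] = np.nan, np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["testable"]
    if mask.any():
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one pathway in one direction."""

    pathway: str
    direction: str  # "up" | "down"
    universe: int   # N: KOs with a differential result
    significant: int  # K: significant KOs in this direction
    pathway_size: int  # n: pathway KOs present in the universe
    overlap: int    # k: significant pathway KOs
    p: float
    q: float = float("nan")


_DIRECTION_MAP = {"up": "increased", "down": "decreased"}


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) — the enrichment p-value."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich_pathway(
    diff: DiffResult,
    pathway_kos: Iterable[str],
    direction: str,
    name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test for over-representation of a pathway's
    KOs among the significantly changed KOs (one direction)."""
    if direction not in _DIRECTION_MAP:
        raise ValueError(f"direction must be 'up' or 'down', got '{direction}'")
    universe = set(diff.table.index)
    if not universe:
        raise ValueError("empty universe: no features with a differential result")
    sig = set(
        diff.table.index[diff.table["direction"] == _DIRECTION_MAP[direction]]
    )
    present = set(pathway_kos) & universe
    k = len(sig & present)
    N, K, n = len(universe), len(sig), len(present)
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(name, direction, N, K, n, k, p)


def enrich_all(
    diff: DiffResult,
    definitions: Sequence[PathwayDef],
    level: str = "subpathway",
) -> pd.DataFrame:
    """Enrichment of every (sub-)pathway in both directions, BH-adjusted
    jointly across pathways × directions."""
    units: list[tuple[str, frozenset[str]]] = []
    for pdef in definitions:
        if level == "pathway":
            units.append((pdef.name, pdef.kos))
        else:
            units.extend((sp.name, sp.kos) for sp in pdef.subpathways)
    results = [
        enrich_pathway(diff, kos, direction, name=name)
        for name, kos in units
        for direction in ("up", "down")
    ]
    q = bh_fdr([r.p for r in results])
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "direction": [r.direction for r in results],
            "N": [r.universe for r in results],
            "K": [r.significant for r in results],
            "n": [r.pathway_size for r in results],
            "k": [r.overlap for r in results],
            "p": [r.p for r in results],
            "q": q,
        }
    )
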