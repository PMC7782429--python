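"""Bin QC, species aggregation, marker-community extraction, partitioning."""

import numpy as np
import pandas as pd
import pytest

from nicomm.abundance import DiffResult
from nicomm.community import (
    BinRecord,
    aggregate_species,
    extract_marker_community,
    filter_bins,
    marker_coverage_fraction,
    partition_populations,
)
from nicomm.markers import MarkerHit, default_marker_catalog, find_marker_genes
from nicomm.synthetic import generate_bins, generate_community


def _bin(bin_id, comp, cont, het, species="sp1", scaffolds=("sc1",)):
    return BinRecord(bin_id, tuple(scaffolds), comp, cont, het, species)


@pytest.mark.parametrize(
    "metrics, kept",
    [
        ((61, 5, 5), True),
        ((60, 5, 5), False),   # completeness boundary is strict
        ((61, 15, 5), False),  # contamination gate
        ((61, 10, 5), False),  # contamination boundary is strict
        ((61, 5, 10), False),  # heterogeneity boundary is strict
        ((100, 0, 0), True),
    ],
)
def test_bin_qc_strict_thresholds(metrics, kept):
    bins = [_bin("b1", *metrics)]
    assert (filter_bins(bins) == bins) is kept


def test_bin_qc_monotone_in_all_thresholds():
    rng = np.random.default_rng(0)
    bins = [
        _bin(f"b{i}", rng.uniform(0, 100), rng.uniform(0, 30), rng.uniform(0, 30))
        for i in range(50)
    ]
    base = set(b.bin_id for b in filter_bins(bins))
    relaxed = set(
        b.bin_id for b in filter_bins(bins, 50, 20, 20)
    )
    assert base <= relaxed
    tightened = set(b.bin_id for b in filter_bins(bins, 70, 5, 5))
    assert tightened <= base


def test_bin_qc_threshold_validation():
    with pytest.raises(ValueError):
        filter_bins([], min_completeness=120)


@pytest.fixture()
def toy_world():
    scaffold_genes = {
        "sc1": ("g1", "g2"),
        "sc2": ("g3",),
        "sc3": ("g4",),
        "sc4": ("g5",),
    }
    ko_map = {"g1": "K00001", "g2": "K00002", "g3": "K00003", "g4": "K00001",
              "g5": "K00004"}
    abundance = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 2.0, 1.0],
            "s2": [20.0, 1.0, 4.0, 3.0],
        },
        index=["sc1", "sc2", "sc3", "sc4"],
    )
    return scaffold_genes, ko_map, abundance


def test_single_bin_aggregate_mirrors_bin(toy_world):
    scaffold_genes, ko_map, abundance = toy_world
    bins = [_bin("b1", 80, 2, 2, "spA", ("sc1", "sc2"))]
    (agg,) = aggregate_species(bins, scaffold_genes, ko_map, abundance)
    assert agg.species == "spA"
    assert agg.avg_completeness == 80
    assert agg.ko_set == {"K00001", "K00002", "K00003"}
    assert agg.abundance.tolist() == [15.0, 21.0]


def test_same_species_bins_summed_with_mean_completeness(toy_world):
    scaffold_genes, ko_map, abundance = toy_world
    bins = [
        _bin("b1", 70, 2, 2, "spA", ("sc1",)),
        _bin("b2", 90, 2, 2, "spA", ("sc2",)),
        _bin("b3", 85, 1, 1, "spB", ("sc3",)),
    ]
    aggs = {a.species: a for a in aggregate_species(bins, scaffold_genes, ko_map, abundance)}
    assert set(aggs) == {"spA", "spB"}
    assert aggs["spA"].avg_completeness == pytest.approx(80.0)
    assert aggs["spA"].abundance.tolist() == [15.0, 21.0]


def test_conflicting_species_claim_names_scaffold(toy_world):
    scaffold_genes, ko_map, abundance = toy_world
    bins = [
        _bin("b1", 70, 2, 2, "spA", ("sc1",)),
        _bin("b2", 90, 2, 2, "spB", ("sc1", "sc2")),
    ]
    with pytest.raises(ValueError, match="sc1"):
        aggregate_species(bins, scaffold_genes, ko_map, abundance)


def test_unclassified_bins_excluded_from_aggregation(toy_world):
    scaffold_genes, ko_map, abundance = toy_world
    bins = [
        _bin("b1", 70, 2, 2, "unclassified", ("sc1",)),
        _bin("b2", 90, 2, 2, "spB", ("sc3",)),
    ]
    aggs = aggregate_species(bins, scaffold_genes, ko_map, abundance)
    assert [a.species for a in aggs] == ["spB"]


def _aggregates(toy_world):
    scaffold_genes, ko_map, abundance = toy_world
    bins = [
        _bin("b1", 80, 2, 2, "spA", ("sc1", "sc2")),
        _bin("b2", 90, 1, 1, "spB", ("sc3",)),
        _bin("b3", 95, 1, 1, "spC", ("sc4",)),
    ]
    return aggregate_species(bins, scaffold_genes, ko_map, abundance)


def test_marker_community_extraction_and_enzyme_complement(toy_world):
    aggs = _aggregates(toy_world)
    gene_scaffold = {"g1": "sc1", "g3": "sc2", "g4": "sc3", "g5": "sc4"}
    hits = [
        MarkerHit("g1", "URE", "K01428", "r", 0.9, 0.95),
        MarkerHit("g3", "LAR", "K22373", "r", 0.9, 0.95),
        MarkerHit("g4", "HYD", "K04651", "r", 0.9, 0.95),
    ]
    community = extract_marker_community(aggs, hits, gene_scaffold)
    by_sp = {a.species: a for a in community}
    # hits on two different scaffolds of spA union into its complement
    assert by_sp["spA"].enzymes == {"URE", "LAR"}
    assert by_sp["spB"].enzymes == {"HYD"}
    # spC owns no marker scaffold and is excluded
    assert "spC" not in by_sp


def test_marker_hit_unresolvable_to_scaffold_rejected(toy_world):
    aggs = _aggregates(toy_world)
    hits = [MarkerHit("gX", "URE", "K01428", "r", 0.9, 0.95)]
    with pytest.raises(ValueError, match="gX"):
        extract_marker_community(aggs, hits, {})


def test_synthetic_truth_recovery_with_perfect_bins(catalog):
    """With complete, uncontaminated, truth-labelled bins the extracted
    marker community is exactly the planted marker species."""
    b = generate_community(n_species=10, seed=21, with_env=False)
    b.bin_table = generate_bins(
        b, completeness_range=(100, 100), contamination_rate=0, seed=22
    )
    from nicomm.pipeline import run_from_bundle

    res = run_from_bundle(b)
    planted = {
        sp for sp, row in b.truth.species_table.iterrows() if row["enzymes"]
    }
    assert {a.species for a in res.marker_community} == planted
    for agg in res.marker_community:
        assert agg.enzymes == frozenset(
            b.truth.species_table.loc[agg.species, "enzymes"]
        )


def _diff_result(rows):
    table = pd.DataFrame(rows).set_index("species")
    table["direction"] = np.where(
        table["q"] < 0.05,
        np.where(table["mean_US"] > table["mean_TP"], "increased", "decreased"),
        "unchanged",
    )
    return DiffResult(table, "TP", "US")


def _community_of(species):
    return [
        # minimal aggregates: only species label matters for partitioning
        type("A", (), {"species": sp})() for sp in species
    ]


def test_population_partition_thresholds():
    diff = _diff_result(
        [
            {"species": "Clostridiales", "mean_TP": 12.24, "mean_US": 48.36, "q": 0.00},
            {"species": "T_succinifaciens", "mean_TP": 1.31, "mean_US": 3.05, "q": 0.07},
            {"species": "P_ruminicola", "mean_TP": 96.46, "mean_US": 27.63, "q": 0.00},
            {"species": "Boundary", "mean_TP": 1.0, "mean_US": 9.0, "q": 0.05},
        ]
    )
    community = _community_of(
        ["Clostridiales", "T_succinifaciens", "P_ruminicola", "Boundary"]
    )
    pops = partition_populations(community, diff)
    assert pops["Clostridiales"] == "upregulated"
    assert pops["T_succinifaciens"] == "unchanged"
    assert pops["P_ruminicola"] == "downregulated"
    assert pops["Boundary"] == "unchanged"  # q = alpha is not significant
    # the three labels partition the community exactly
    assert set(pops) == {a.species for a in community}


def test_partition_missing_species_rejected():
    diff = _diff_result([{"species": "a", "mean_TP": 1, "mean_US": 2, "q": 0.5}])
    with pytest.raises(ValueError, match="b"):
        partition_populations(_community_of(["a", "b"]), diff)


def _coverage_setup(binned_genes):
    hits = [
        MarkerHit(g, "URE", "K01428", "r", 0.9, 0.95)
        for g in ["g1", "g2", "g3", "g4"]
    ]
    gene_scaffold = {g: f"sc_{g}" for g in ["g1", "g2", "g3", "g4"]}
    qc_bins = (
        [_bin("b1", 90, 1, 1, "spA", tuple(f"sc_{g}" for g in binned_genes))]
        if binned_genes
        else []
    )
    abundance = pd.DataFrame(
        {"s1": [2.0, 2.0, 2.0, 2.0], "s2": [1.0, 1.0, 1.0, 1.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    return hits, qc_bins, abundance, gene_scaffold


@pytest.mark.parametrize(
    "binned, expected",
    [
        (["g1", "g2", "g3", "g4"], 1.0),
        ([], 0.0),
        (["g1", "g2"], 0.5),
    ],
)
def test_marker_coverage_fraction(binned, expected):
    hits, qc_bins, abundance, gene_scaffold = _coverage_setup(binned)
    frac, (lo, hi) = marker_coverage_fraction(
        hits, qc_bins, abundance, gene_scaffold, "URE"
    )
    assert lo == pytest.approx(expected) and hi == pytest.approx(expected)


def test_marker_coverage_zero_abundance_sample_excluded_with_warning():
    hits, qc_bins, abundance, gene_scaffold = _coverage_setup(["g1", "g2"])
    abundance["s2"] = 0.0
    with pytest.warns(UserWarning, match="s2"):
        frac, (lo, hi) = marker_coverage_fraction(
            hits, qc_bins, abundance, gene_scaffold, "URE"
        )
    assert np.isnan(frac["s2"])
    assert lo == hi == pytest.approx(0.5)
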