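"""Pathway definitions, completeness statistic, ANOVA, enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from nicomm.abundance import DiffResult
from nicomm.pathways import (
    PEG,
    compare_populations,
    completeness_table,
    detect_kos,
    detect_pegs,
    enrich_all,
    enrich_pathway,
    load_pathway_definitions,
    pathway_completeness,
)

SCFA_SUBPATHWAYS = [
    "Starch degradation",
    "Glycolysis",
    "Cellulose degradation",
    "Hemicellulose degradation",
    "Pectin degradation",
    "Propionate generation",
    "Butyrate generation",
    "Acetate generation",
    "Formate generation",
    "Lactate metabolism",
]


def test_bundled_scfa_definition_layout(pathway_defs):
    scfa = next(p for p in pathway_defs if p.id == "scfa_generation")
    assert [sp.name for sp in scfa.subpathways] == SCFA_SUBPATHWAYS
    codes = {peg.code for sp in scfa.subpathways for peg in sp.pegs}
    assert len(codes) == 62
    # shared steps: 27-32 in hemicellulose and pectin, 44/46 in
    # propionate and acetate generation, each with one KO set
    by_name = {sp.name: sp for sp in scfa.subpathways}
    hemi = {p.code for p in by_name["Hemicellulose degradation"].pegs}
    pectin = {p.code for p in by_name["Pectin degradation"].pegs}
    assert set(range(27, 33)) <= hemi & pectin
    prop = {p.code for p in by_name["Propionate generation"].pegs}
    acet = {p.code for p in by_name["Acetate generation"].pegs}
    assert {44, 46} <= prop & acet
    # auxiliary pathways bundled alongside
    names = {p.id for p in pathway_defs}
    assert {"fatty_acid_biosynthesis", "nitrogen_metabolism", "sulfur_metabolism"} <= names


@pytest.mark.parametrize(
    "content, message",
    [
        ("", "empty"),
        ("pathways: []", "no 'pathways'"),
        (
            "pathways:\n- id: p\n  subpathways:\n  - name: a\n    pegs:\n"
            "    - {code: 1, kos: [X123]}\n",
            "malformed KO",
        ),
        (
            "pathways:\n- id: p\n  subpathways:\n  - name: a\n    pegs:\n"
            "    - {code: 1, kos: [K00001]}\n    - {code: 1, kos: [K00002]}\n",
            "re-used with a different KO set",
        ),
        (
            "pathways:\n- id: p\n  subpathways:\n  - name: a\n    pegs: []\n"
            "  - name: a\n    pegs: []\n",
            "duplicate sub-pathway",
        ),
        (
            "pathways:\n- id: p\n  subpathways:\n  - name: a\n    pegs:\n"
            "    - {code: 1, kos: []}\n",
            "no KO ids",
        ),
    ],
)
def test_definition_parse_errors(tmp_path, content, message):
    path = tmp_path / "defs.yaml"
    path.write_text(content)
    with pytest.raises(ValueError, match=message):
        load_pathway_definitions(path)


def test_detect_pegs_set_semantics():
    pegs = [
        PEG(1, frozenset({"K00001", "K00002", "K00003"})),
        PEG(2, frozenset({"K00004"})),
        PEG(3, frozenset({"K00005"})),
    ]
    assert detect_pegs([], pegs) == 0
    assert detect_pegs(["K00009"], pegs) == 0
    # two interchangeable KOs of one PEG count once
    assert detect_pegs(["K00001", "K00002"], pegs) == 1
    assert detect_pegs(["K00001", "K00004", "K00005"], pegs) == 3
    # KO-level counting distinguishes the same case
    assert detect_kos(["K00001", "K00002"], pegs) == 2


@pytest.mark.parametrize(
    "pegs, completeness, expected",
    [
        (12, 0.80, 15.0),
        (0, 0.35, 0.0),
        (7, 1.0, 7.0),
    ],
)
def test_pathway_completeness_statistic(pegs, completeness, expected):
    assert pathway_completeness(pegs, completeness) == pytest.approx(expected)


def test_pathway_completeness_bounds():
    with pytest.raises(ValueError):
        pathway_completeness(3, 0.0)
    with pytest.raises(ValueError):
        pathway_completeness(3, 1.2)
    # antitone in completeness at fixed PEG count, floored at the raw count
    values = [pathway_completeness(10, c) for c in (0.5, 0.7, 0.9, 1.0)]
    assert values == sorted(values, reverse=True)
    assert values[-1] == 10


def _anova_oracle(groups):
    """Brute-force one-way ANOVA from the sum-of-squares decomposition."""
    flat = np.concatenate(groups)
    grand = flat.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((flat - grand) ** 2).sum()
    assert ss_total == pytest.approx(ss_between + ss_within, rel=1e-9)
    df_b = len(groups) - 1
    df_w = len(flat) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def _records(values_by_species, pathway="P", subpathway="sub"):
    return pd.DataFrame(
        [
            {
                "species": sp,
                "pathway": pathway,
                "subpathway": subpathway,
                "detected_pegs": 0,
                "avg_completeness": 1.0,
                "statistic": v,
            }
            for sp, v in values_by_species.items()
        ]
    )


def test_anova_identical_values_give_zero_f_unit_p():
    records = _records({f"s{i}": 4.2 for i in range(6)})
    pops = {f"s{i}": ["a", "b", "c"][i % 3] for i in range(6)}
    out = compare_populations(records, pops)
    assert out.loc[0, "F"] == 0.0 and out.loc[0, "p"] == 1.0


def test_anova_matches_sum_of_squares_oracle():
    rng = np.random.default_rng(8)
    groups = [rng.normal(loc, 1.0, size=5) for loc in (0.0, 0.8, 2.0)]
    values = {}
    pops = {}
    for gi, g in enumerate(groups):
        for i, v in enumerate(g):
            sp = f"s{gi}_{i}"
            values[sp] = v
            pops[sp] = f"pop{gi}"
    out = compare_populations(_records(values), pops)
    assert out.loc[0, "F"] == pytest.approx(_anova_oracle(groups), rel=1e-9)


def test_butyrate_style_comparison_orders_population_means():
    """A fixture mirroring the butyrate-generation contrast (means ~7.1 /
    3.1 / 2.3) ranks the upregulated population highest and is significant."""
    rng = np.random.default_rng(3)
    values, pops = {}, {}
    for label, mean in (("upregulated", 7.10), ("downregulated", 3.09), ("unchanged", 2.31)):
        for i in range(5):
            sp = f"{label}_{i}"
            values[sp] = mean + rng.normal(0, 0.6)
            pops[sp] = label
    out = compare_populations(_records(values), pops)
    row = out.iloc[0]
    assert row["mean_upregulated"] > max(row["mean_downregulated"], row["mean_unchanged"])
    assert row["q"] < 0.05


def test_small_population_flagged_untestable():
    records = _records({"a": 1.0, "b": 2.0, "c": 3.0})
    pops = {"a": "up", "b": "up", "c": "down"}  # 'down' has a single member
    out = compare_populations(records, pops)
    assert not out.loc[0, "testable"]
    assert np.isnan(out.loc[0, "q"])


def _diff_from_kos(universe, sig_up):
    table = pd.DataFrame(
        {
            "mean_TP": 1.0,
            "mean_US": 2.0,
            "p": 0.5,
            "q": [0.01 if k in sig_up else 0.5 for k in universe],
            "direction": ["increased" if k in sig_up else "unchanged" for k in universe],
        },
        index=universe,
    )
    return DiffResult(table, "TP", "US")


def _enum_upper_tail(N, K, n, k):
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)


def test_enrichment_zero_overlap_gives_p_one():
    universe = [f"K{i:05d}" for i in range(20)]
    diff = _diff_from_kos(universe, set(universe[:5]))
    res = enrich_pathway(diff, universe[10:14], "up")
    assert res.overlap == 0 and res.p == 1.0


def test_enrichment_degenerate_support_gives_p_one():
    universe = [f"K{i:05d}" for i in range(6)]
    diff = _diff_from_kos(universe, set(universe))
    res = enrich_pathway(diff, universe, "up")
    assert (res.universe, res.significant, res.pathway_size, res.overlap) == (6, 6, 6, 6)
    assert res.p == pytest.approx(1.0)


def test_enrichment_matches_enumeration_and_monotone_in_overlap():
    universe = [f"K{i:05d}" for i in range(100)]
    sig = set(universe[:10])
    pathway = universe[5:15]  # n = 10, overlap k = 5
    diff = _diff_from_kos(universe, sig)
    res = enrich_pathway(diff, pathway, "up")
    assert res.overlap == 5
    assert res.p == pytest.approx(_enum_upper_tail(100, 10, 10, 5), rel=1e-12)
    # p non-increasing as overlap grows at fixed N, K, n
    ps = []
    for k in range(0, 11):
        pathway_k = universe[10 - k : 20 - k]  # shifts overlap with sig
        ps.append(enrich_pathway(diff, pathway_k, "up").p)
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_enrichment_empty_universe_rejected():
    diff = _diff_from_kos([], set())
    with pytest.raises(ValueError, match="empty universe"):
        enrich_pathway(diff, ["K00001"], "up")
    with pytest.raises(ValueError, match="direction"):
        enrich_pathway(_diff_from_kos(["K00001"], set()), [], "sideways")


def test_enrich_all_adjusts_jointly_across_pathways_and_directions(pathway_defs):
    universe = sorted({ko for p in pathway_defs for ko in p.kos})
    diff = _diff_from_kos(universe, set(universe[:15]))
    out = enrich_all(diff, pathway_defs)
    assert set(out["direction"]) == {"up", "down"}
    n_units = sum(len(p.subpathways) for p in pathway_defs)
    assert len(out) == 2 * n_units
    assert (out["q"] >= out["p"] - 1e-15).all()


def test_completeness_table_counting_units(pathway_defs):
    scfa = next(p for p in pathway_defs if p.id == "scfa_generation")
    glyco = next(sp for sp in scfa.subpathways if sp.name == "Glycolysis")
    kos = set(list(glyco.kos)[:4])
    peg_tab = completeness_table({"sp": kos}, {"sp": 0.8}, [scfa], count="peg")
    ko_tab = completeness_table({"sp": kos}, {"sp": 0.8}, [scfa], count="ko")
    row = peg_tab[peg_tab["subpathway"] == "Glycolysis"].iloc[0]
    row_ko = ko_tab[ko_tab["subpathway"] == "Glycolysis"].iloc[0]
    assert row_ko["detected_pegs"] == 4
    assert row["detected_pegs"] <= 4
    assert row["statistic"] == pytest.approx(row["detected_pegs"] / 0.8)
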