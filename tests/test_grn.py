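"""GRN inference: TF/site filtering, gene assignment, interaction scores,
network construction, differential connectivity."""

import numpy as np
import pandas as pd
import pytest

import atacohort as a
from atacohort.grn import site_weight


def _sites(rows):
    return pd.DataFrame(rows, columns=["tf", "chrom", "start", "end", "purity"])


def _genes(rows):
    g = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
    return g


PEAK = [a.GenomicRegion("chr1", 0, 1_000_000)]


def test_filter_boundaries():
    # exactly 500 qualifying sites at purity just above 0.7 -> retained
    rows = [("T1", "chr1", 100 + i, 115 + i, 0.71) for i in range(500)]
    kept = a.filter_tfs(_sites(rows), PEAK)
    assert kept["tf"].nunique() == 1 and len(kept) == 500

    # 499 qualifying sites -> excluded
    kept = a.filter_tfs(_sites(rows[:499]), PEAK)
    assert kept.empty

    # purity exactly 0.7 does not qualify (strict >)
    rows_07 = [("T1", "chr1", 100 + i, 115 + i, 0.70) for i in range(600)]
    assert a.filter_tfs(_sites(rows_07), PEAK).empty


def test_filter_requires_peak_overlap():
    rows = [("T1", "chr1", 2_000_000 + i, 2_000_015 + i, 0.9) for i in range(600)]
    assert a.filter_tfs(_sites(rows), PEAK).empty  # outside the peak
    with pytest.raises(ValueError):
        a.filter_tfs(_sites(rows), [])


def test_assignment_classes():
    genes = _genes([("GA", "chr1", 10_000, 20_000, "+")])
    sites = _sites(
        [
            ("T1", "chr1", 15_000, 15_015, 0.9),  # inside the body
            ("T1", "chr1", 8_000, 8_015, 0.9),  # 2,000 bp upstream of the + TSS
            ("T1", "chr1", 100_000, 100_015, 0.9),  # intergenic
        ]
    )
    out = a.assign_sites_to_genes(sites, genes).set_index("site_index")
    assert out.loc[0, "assignment"] == "body"
    assert out.loc[1, "assignment"] == "upstream"
    assert out.loc[1, "distance"] == pytest.approx(10_000 - 8_007.5)
    assert out.loc[2, "assignment"] == "intergenic-nearest"
    assert out.loc[2, "gene_id"] == "GA"


def test_assignment_strand_aware_upstream():
    genes = _genes([("GB", "chr1", 10_000, 20_000, "-")])  # TSS at 19,999
    down = _sites([("T1", "chr1", 21_000, 21_015, 0.9)])  # upstream for - strand
    out = a.assign_sites_to_genes(down, genes)
    assert out.iloc[0]["assignment"] == "upstream"
    up = _sites([("T1", "chr1", 30_000, 30_015, 0.9)])  # beyond 2,500 bp
    out = a.assign_sites_to_genes(up, genes)
    assert out.iloc[0]["assignment"] == "intergenic-nearest"


def test_assignment_unassigned_flagged():
    genes = _genes([("GA", "chr1", 0, 1000, "+")])
    sites = _sites([("T1", "chr9", 100, 115, 0.9)])
    out = a.assign_sites_to_genes(sites, genes)
    assert out.iloc[0]["assignment"] == "unassigned"
    assert pd.isna(out.iloc[0]["gene_id"]) or out.iloc[0]["gene_id"] is None


def test_intergenic_assignment_matches_bruteforce():
    rng = np.random.default_rng(33)
    genes = _genes(
        [
            (f"G{i}", "chr1", int(p), int(p) + 500, "+")
            for i, p in enumerate(sorted(rng.integers(0, 500_000, size=6)))
        ]
    )
    for _ in range(100):
        start = int(rng.integers(0, 500_000))
        sites = _sites([("T1", "chr1", start, start + 15, 0.9)])
        out = a.assign_sites_to_genes(sites, genes)
        intergenic = out[out["assignment"] == "intergenic-nearest"]
        if intergenic.empty:
            continue
        mid = start + 7.5
        dists = {row["gene_id"]: abs(mid - row["tss"]) for _, row in genes.iterrows()}
        dmin = min(dists.values())
        best = min(g for g, d in dists.items() if d == dmin)
        assert intergenic.iloc[0]["gene_id"] == best


def test_site_weight_maximum_and_examples():
    assert site_weight(1.0, 0.0) == pytest.approx(1.0)
    assert site_weight(0.5, 0.0) == pytest.approx(0.0)  # chance-level purity
    assert site_weight(1.0, 1e6) == pytest.approx(0.1)  # one decade per Mb


def _assignments(rows):
    return pd.DataFrame(
        rows, columns=["site_index", "tf", "gene_id", "distance", "assignment", "purity"]
    )


def test_interaction_scores_additive_and_match_resummation():
    rng = np.random.default_rng(44)
    rows = []
    for i in range(5):
        rows.append((i, "T1", "GA", float(rng.integers(0, 50_000)),
                     "body", float(rng.uniform(0.71, 1.0))))
    table = a.interaction_scores(_assignments(rows))
    oracle = sum(
        2 * (p - 0.5) * 10 ** (-d / 1e6) for _, _, _, d, _, p in rows
    )
    assert table.iloc[0]["score"] == pytest.approx(oracle)
    # additivity: splitting the site set and summing partials is exact
    part1 = a.interaction_scores(_assignments(rows[:2])).iloc[0]["score"]
    part2 = a.interaction_scores(_assignments(rows[2:])).iloc[0]["score"]
    assert part1 + part2 == pytest.approx(table.iloc[0]["score"])


def test_interaction_scores_monotone_in_purity_and_distance():
    base = _assignments([(0, "T1", "GA", 1000.0, "body", 0.8)])
    s0 = a.interaction_scores(base).iloc[0]["score"]
    higher_p = _assignments([(0, "T1", "GA", 1000.0, "body", 0.9)])
    closer = _assignments([(0, "T1", "GA", 100.0, "body", 0.8)])
    assert a.interaction_scores(higher_p).iloc[0]["score"] >= s0
    assert a.interaction_scores(closer).iloc[0]["score"] >= s0


def test_interaction_scores_absent_pair_is_absent():
    table = a.interaction_scores(_assignments([]))
    assert table.empty


def test_build_network_threshold_and_handshake():
    scores = pd.DataFrame(
        {"tf": ["T1", "T1"], "gene_id": ["GA", "GB"], "score": [1.2, 0.9]}
    )
    net = a.build_network(scores)
    assert net.n_edges == 1
    assert list(net.graph.edges()) == [("T1", "GA")]
    out_deg = sum(d for _, d in net.graph.out_degree())
    in_deg = sum(d for _, d in net.graph.in_degree())
    assert out_deg == in_deg == net.n_edges

    empty = a.build_network(scores.assign(score=[1.0, 0.5]))  # 1 is not above 1
    assert empty.n_edges == 0


def _net(edges):
    scores = pd.DataFrame(
        [(t, g, 2.0) for t, g in edges], columns=["tf", "gene_id", "score"]
    )
    return a.build_network(scores)


def test_differential_connectivity_examples():
    net = _net([("T1", "G1"), ("T1", "G2"), ("T2", "G1")])
    diff = a.differential_connectivity(net, net)
    shared = diff[diff["presence"] == "both"]
    assert np.allclose(shared["log2_change"], 0.0)

    # degree 2 of 10 edges vs 1 of 10 edges -> log2(0.2/0.1) = 1
    net_a = _net([("T1", f"G{i}") for i in range(2)] + [("T9", f"H{i}") for i in range(8)])
    net_b = _net([("T1", "G0")] + [("T9", f"H{i}") for i in range(9)])
    diff = a.differential_connectivity(net_a, net_b).set_index("node")
    assert diff.loc["T1", "log2_change"] == pytest.approx(1.0)


def test_differential_connectivity_antisymmetric_and_scale_invariant():
    net_a = _net([("T1", "G1"), ("T1", "G2"), ("T2", "G3")])
    net_b = _net([("T1", "G1"), ("T2", "G2"), ("T2", "G3"), ("T3", "G1")])
    ab = a.differential_connectivity(net_a, net_b).set_index("node")["log2_change"]
    ba = a.differential_connectivity(net_b, net_a).set_index("node")["log2_change"]
    both = ab.dropna().index
    assert np.allclose(ab[both], -ba[both])

    doubled = _net(
        [("T1", "G1"), ("T1", "G2"), ("T2", "G3"), ("T1", "H1"), ("T1", "H2"), ("T2", "H3")]
    )
    # doubling degrees and totals together leaves normalized changes intact
    d1 = a.differential_connectivity(net_a, net_b).set_index("node")["log2_change"]
    d2 = a.differential_connectivity(doubled, net_b).set_index("node")["log2_change"]
    assert np.allclose(d1["T1"], d2["T1"])


def test_filter_soundness_on_synthetic_footprints(small_cohort):
    cons = a.merge_peak_sets(small_cohort.peak_sets)
    kept = a.filter_tfs(small_cohort.footprints, cons.regions)
    assert (kept["purity"] > 0.7).all()
    assert (kept["tf"].value_counts() >= 500).all()


def test_planted_network_recovery(small_cohort):
    """Planted TF->gene pairs exceed the edge threshold; decoy TFs with
    distal low-evidence sites do not."""
    cons = a.merge_peak_sets(small_cohort.peak_sets)
    kept = a.filter_tfs(small_cohort.footprints, cons.regions)
    assigned = a.assign_sites_to_genes(kept, small_cohort.gene_models)
    net = a.build_network(a.interaction_scores(assigned))
    edges = set(net.graph.edges())
    planted = {tuple(e) for e in small_cohort.ground_truth["planted_edges"]}
    decoys = set(small_cohort.ground_truth["decoy_tfs"])
    assert len(planted & edges) >= 0.9 * len(planted)
    decoy_edges = [e for e in edges if e[0] in decoys]
    assert len(decoy_edges) == 0
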