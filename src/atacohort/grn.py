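"""Footprint-based gene-regulatory-network inference and differential
connectivity.

Transcription-factor footprints (with a caller confidence, the purity
score) are filtered to high-purity sites inside accessible chromatin,
assigned to genes (gene body or 2,500 bp upstream of the TSS, else nearest
TSS), and aggregated into a purity-weighted, distance-decayed interaction
score per TF-gene pair.  Pairs scoring above a threshold become directed
edges; two networks are compared by the log2 ratio of edge-count-normalized
node degrees.

The per-site weight is w(P, d) = 2(P - 0.5) * 10^(-d / 1e6): it vanishes at
the chance-level purity 0.5, reaches 1 for a perfectly pure site at the
TSS, and decays tenfold per megabase.  Both the purity transform offset and
the decay constant are configurable and recorded in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .regions import GenomicRegion, merge_intervals

MIN_SITES = 500
PURITY_MIN = 0.7
EDGE_THRESHOLD = 1.0
UPSTREAM_BP = 2500
DISTANCE_DECAY_BP = 1e6
PURITY_OFFSET = 0.5


def filter_tfs(
    sites: pd.DataFrame,
    peaks: list[GenomicRegion],
    min_sites: int = MIN_SITES,
    purity_min: float = PURITY_MIN,
) -> pd.DataFrame:
    """Keep high-purity sites in accessible chromatin of well-supported TFs.

    A site qualifies iff purity > purity_min (strict) and it overlaps >=1
    peak by >=1 bp; a TF is retained iff it has >= min_sites qualifying
    sites.  Only qualifying sites of retained TFs are returned.
    """
    if not peaks:
        raise ValueError("empty peak set")
    high = sites[sites["purity"] > purity_min]
    # merged peaks are non-overlapping, so a sorted binary search suffices
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p in merge_intervals(peaks):
        index.setdefault(p.chrom, ([], []))
        index[p.chrom][0].append(p.start)
        index[p.chrom][1].append(p.end)
    index = {c: (np.array(s), np.array(e)) for c, (s, e) in index.items()}
    in_peak = np.zeros(len(high), dtype=bool)
    for k, (c, s, e) in enumerate(
        zip(high["chrom"], high["start"], high["end"])
    ):
        if c not in index:
            continue
        starts, ends = index[c]
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        in_peak[k] = lo < hi
    qualifying = high[in_peak]
    counts = qualifying["tf"].value_counts()
    retained = counts.index[counts >= min_sites]
    return qualifying[qualifying["tf"].isin(retained)].reset_index(drop=True)


def assign_sites_to_genes(
    sites: pd.DataFrame, genes: pd.DataFrame, upstream_bp: int = UPSTREAM_BP
) -> pd.DataFrame:
    """Assign each footprint site to target gene(s).

    A site inside a gene body, or within ``upstream_bp`` upstream of the TSS
    (strand-aware), is assigned to every such gene (class body/upstream); an
    intergenic site goes to the single gene with the nearest TSS by
    site-midpoint distance (lexicographic gene-ID tie-break).  The distance
    d = |site midpoint - TSS| accompanies every assignment.  Sites on
    chromosomes without genes are flagged unassigned.
    """
    rows = []
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for i, site in sites.iterrows():
        g = genes_by_chrom.get(site["chrom"])
        if g is None:
            rows.append(
                {
                    "site_index": i,
                    "tf": site["tf"],
                    "gene_id": None,
                    "distance": np.nan,
                    "assignment": "unassigned",
                    "purity": site["purity"],
                }
            )
            continue
        mid = (site["start"] + site["end"]) / 2
        assigned = False
        for _, gene in g.iterrows():
            in_body = site["start"] < gene["end"] and site["end"] > gene["start"]
            if gene["strand"] == "+":
                up_lo, up_hi = gene["tss"] - upstream_bp, gene["tss"]
            else:
                up_lo, up_hi = gene["tss"] + 1, gene["tss"] + 1 + upstream_bp
            in_upstream = site["start"] < up_hi and site["end"] > up_lo
            if in_body or in_upstream:
                rows.append(
                    {
                        "site_index": i,
                        "tf": site["tf"],
                        "gene_id": gene["gene_id"],
                        "distance": abs(mid - gene["tss"]),
                        "assignment": "body" if in_body else "upstream",
                        "purity": site["purity"],
                    }
                )
                assigned = True
        if assigned:
            continue
        dist = np.abs(mid - g["tss"].to_numpy())
        dmin = dist.min()
        best = g[dist == dmin].sort_values("gene_id").iloc[0]
        rows.append(
            {
                "site_index": i,
                "tf": site["tf"],
                "gene_id": best["gene_id"],
                "distance": float(dmin),
                "assignment": "intergenic-nearest",
                "purity": site["purity"],
            }
        )
    return pd.DataFrame(rows)


def site_weight(
    purity: np.ndarray,
    distance: np.ndarray,
    purity_offset: float = PURITY_OFFSET,
    decay_bp: float = DISTANCE_DECAY_BP,
) -> np.ndarray:
    """Per-site evidence weight: purity above chance, decayed with distance."""
    p = np.asarray(purity, dtype=float)
    d = np.asarray(distance, dtype=float)
    return 2 * (p - purity_offset) * np.power(10.0, -d / decay_bp)


def interaction_scores(
    assignments: pd.DataFrame,
    purity_offset: float = PURITY_OFFSET,
    decay_bp: float = DISTANCE_DECAY_BP,
) -> pd.DataFrame:
    """Sum per-site weights over all sites assigned to each (TF, gene) pair."""
    valid = assignments.dropna(subset=["gene_id"]).copy()
    if valid.empty:
        return pd.DataFrame(columns=["tf", "gene_id", "score", "n_sites"])
    valid["w"] = site_weight(
        valid["purity"].to_numpy(),
        valid["distance"].to_numpy(),
        purity_offset,
        decay_bp,
    )
    out = (
        valid.groupby(["tf", "gene_id"], as_index=False)
        .agg(score=("w", "sum"), n_sites=("w", "size"))
        .sort_values(["tf", "gene_id"])
        .reset_index(drop=True)
    )
    return out


@dataclass
class RegulatoryNetwork:
    graph: nx.DiGraph
    edge_threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree")


def build_network(
    scores: pd.DataFrame, edge_threshold: float = EDGE_THRESHOLD
) -> RegulatoryNetwork:
    """Directed TF->gene network from interaction scores strictly above the
    threshold; nodes with no surviving edge are dropped."""
    g = nx.DiGraph()
    kept = scores[scores["score"] > edge_threshold]
    for _, row in kept.iterrows():
        g.add_edge(row["tf"], row["gene_id"], score=float(row["score"]))
    return RegulatoryNetwork(
        graph=g,
        edge_threshold=edge_threshold,
        metadata={
            "purity_offset": PURITY_OFFSET,
            "distance_decay_bp": DISTANCE_DECAY_BP,
        },
    )


def differential_connectivity(
    net_a: RegulatoryNetwork, net_b: RegulatoryNetwork
) -> pd.DataFrame:
    """log2 change of edge-count-normalized node degree between networks.

    Normalized degree = (in+out degree) / total edges of the node's network;
    the log2 ratio A/B is reported for nodes present in both networks,
    ranked by |change|.  Nodes in only one network are flagged with the
    network they belong to and NaN change.
    """
    if net_a.n_edges == 0 or net_b.n_edges == 0:
        raise ValueError("both networks must be non-empty")
    deg_a = net_a.degrees() / net_a.n_edges
    deg_b = net_b.degrees() / net_b.n_edges
    nodes = sorted(set(deg_a.index) | set(deg_b.index))
    rows = []
    for node in nodes:
        in_a, in_b = node in deg_a.index, node in deg_b.index
        change = (
            float(np.log2(deg_a[node] / deg_b[node])) if in_a and in_b else np.nan
        )
        rows.append(
            {
                "node": node,
                "norm_degree_a": deg_a[node] if in_a else np.nan,
                "norm_degree_b": deg_b[node] if in_b else np.nan,
                "log2_change": change,
                "presence": "both" if in_a and in_b else ("a_only" if in_a else "b_only"),
            }
        )
    out = pd.DataFrame(rows)
    out["abs_change"] = out["log2_change"].abs()
    out = out.sort_values("abs_change", ascending=False, na_position="last")
    return out.drop(columns="abs_change").reset_index(drop=True)
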