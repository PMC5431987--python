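"""Chromosomal classification and topology of co-expression networks.

The headline contrast this module quantifies: in the healthy-phenotype
network, strong gene-gene dependencies connect chromosomes genome-wide,
whereas in the tumour network they collapse into small connected components
of neighbouring genes on a single chromosome, each coherently over- or
under-expressed. Edges are classified intra- vs inter-chromosomal, whole
networks and individual components are profiled, intra-chromosomal genomic
distances summarized, subsample robustness assessed, and (optionally) edges
scored against an external chromatin-contact table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import estimate_mi, threshold_top_fraction

logger = logging.getLogger(__name__)


class TopologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Edge classification

@dataclass
class EdgeClassification:
    """Per-edge intra/inter labels and intra-chromosomal genomic distances.

    ``edges`` columns: gene_a, gene_b (lexicographic order), mi, chrom_a,
    chrom_b, label ('intra'|'inter'), distance (bp between interval midpoints;
    NaN for inter edges).
    """

    edges: pd.DataFrame
    inter_fraction: float
    intra_counts: pd.Series  # intra edges per chromosome
    n_inter: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def classify_edges(net: nx.Graph, ann: pd.DataFrame) -> EdgeClassification:
    """Label every edge intra- or inter-chromosomal.

    Genomic distance of an intra edge is the absolute difference of the two
    gene interval midpoints (1-based inclusive coordinates). Raises if any
    network gene is missing from the annotation, listing the offenders.
    """
    a = ann.drop_duplicates("gene_id").set_index("gene_id")
    missing = [n for n in net.nodes if n not in a.index]
    if missing:
        raise TopologyError(f"unannotated network genes: {sorted(missing)[:10]}")
    chrom = a["chromosome"].astype(str)
    mid = (a["start"] + a["end"]) / 2.0

    rows = []
    for u, v, d in net.edges(data=True):
        u, v = (u, v) if u <= v else (v, u)
        cu, cv = chrom[u], chrom[v]
        intra = cu == cv
        rows.append(
            (
                u,
                v,
                d.get("mi", np.nan),
                cu,
                cv,
                "intra" if intra else "inter",
                abs(mid[u] - mid[v]) if intra else np.nan,
            )
        )
    edges = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "mi", "chrom_a", "chrom_b", "label", "distance"]
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    n_inter = int((edges["label"] == "inter").sum())
    inter_fraction = n_inter / len(edges) if len(edges) else float("nan")
    intra_counts = (
        edges.loc[edges["label"] == "intra", "chrom_a"].value_counts().rename("n_intra_edges")
    )
    return EdgeClassification(
        edges=edges,
        inter_fraction=inter_fraction,
        intra_counts=intra_counts,
        n_inter=n_inter,
    )


# ---------------------------------------------------------------------------
# Whole-network topology

@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_components: int
    largest_component: int
    diameter: int
    connected_pairs: int
    avg_shortest_path: float
    avg_degree: float
    density: float
    clustering_coefficient: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Component structure, distances, density and clustering of a network.

    The diameter is that of the largest connected component (the convention
    for disconnected graphs); the average shortest path length is averaged
    over connected pairs only; the clustering coefficient is the mean local
    clustering with degree-<2 nodes contributing 0.
    """
    if net.number_of_nodes() == 0:
        raise TopologyError("empty network")
    N = net.number_of_nodes()
    E = net.number_of_edges()
    comps = [net.subgraph(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda g: g.number_of_nodes(), reverse=True)
    largest = comps[0]
    connected_pairs = sum(math.comb(g.number_of_nodes(), 2) for g in comps)
    path_sum = 0.0
    for g in comps:
        m = g.number_of_nodes()
        if m >= 2:
            path_sum += nx.average_shortest_path_length(g) * math.comb(m, 2)
    return TopologySummary(
        n_nodes=N,
        n_edges=E,
        n_components=len(comps),
        largest_component=largest.number_of_nodes(),
        diameter=nx.diameter(largest) if largest.number_of_nodes() > 1 else 0,
        connected_pairs=connected_pairs,
        avg_shortest_path=path_sum / connected_pairs if connected_pairs else float("nan"),
        avg_degree=2 * E / N,
        density=2 * E / (N * (N - 1)) if N > 1 else 0.0,
        clustering_coefficient=float(np.mean(list(nx.clustering(net).values()))),
    )


# ---------------------------------------------------------------------------
# Component profiling

@dataclass
class ComponentProfile:
    genes: tuple[str, ...]
    size: int
    n_edges: int
    density: float
    dominant_chromosome: str
    chromosome_homogeneity: float
    de_sign_homogeneity: float
    contains_tf: bool

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["genes"] = ";".join(self.genes)
        return d


def component_profiles(
    net: nx.Graph, de=None, ann: pd.DataFrame | None = None
) -> list[ComponentProfile]:
    """Profile each connected component, ranked by density.

    Chromosome homogeneity is the largest per-chromosome share of members;
    DE-sign homogeneity the larger of the shares with log2FC > 0 and < 0.
    Attributes are read from the node data (see
    :func:`chromonet.network.annotate_network`) unless ``ann``/``de``
    override them. Sorted descending by density, ties by size then by
    lexicographically smallest member.
    """
    chrom = None if ann is None else ann.drop_duplicates("gene_id").set_index("gene_id")[
        "chromosome"
    ].astype(str)
    lfc = None if de is None else de.table["log2fc"]

    profiles = []
    for members in nx.connected_components(net):
        sub = net.subgraph(members)
        genes = tuple(sorted(members))
        size = len(genes)
        n_edges = sub.number_of_edges()
        density = n_edges / math.comb(size, 2) if size > 1 else 1.0

        chroms = []
        for g in genes:
            c = chrom.get(g) if chrom is not None else net.nodes[g].get("chromosome")
            if c is not None:
                chroms.append(str(c))
        if chroms:
            counts = pd.Series(chroms).value_counts()
            dominant, chom = str(counts.index[0]), counts.iloc[0] / len(chroms)
        else:
            dominant, chom = "NA", float("nan")

        lfcs = []
        for g in genes:
            v = lfc.get(g) if lfc is not None else net.nodes[g].get("log2fc")
            if v is not None and not pd.isna(v):
                lfcs.append(float(v))
        if lfcs:
            up = sum(v > 0 for v in lfcs)
            down = sum(v < 0 for v in lfcs)
            sign_hom = max(up, down) / len(lfcs)
        else:
            sign_hom = float("nan")

        contains_tf = any(net.nodes[g].get("is_tf", False) for g in genes)
        profiles.append(
            ComponentProfile(
                genes=genes,
                size=size,
                n_edges=n_edges,
                density=density,
                dominant_chromosome=dominant,
                chromosome_homogeneity=chom,
                de_sign_homogeneity=sign_hom,
                contains_tf=contains_tf,
            )
        )
    profiles.sort(key=lambda p: (-p.density, -p.size, p.genes[0]))
    return profiles


def write_component_profiles(profiles: list[ComponentProfile], path) -> None:
    pd.DataFrame([p.to_dict() for p in profiles]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intra-chromosomal distance profile

@dataclass
class DistanceSummary:
    n_intra: int
    median: float
    iqr: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    per_chromosome_median: pd.Series


def intra_distance_profile(ec: EdgeClassification, n_hist_bins: int = 20) -> DistanceSummary:
    """Genomic-distance distribution of intra-chromosomal edges.

    Returns an empty summary (n_intra = 0, NaN statistics) when the network
    has no intra edges.
    """
    d = ec.edges.loc[ec.edges["label"] == "intra", ["chrom_a", "distance"]]
    if d.empty:
        return DistanceSummary(
            n_intra=0,
            median=float("nan"),
            iqr=float("nan"),
            histogram_counts=np.array([], dtype=int),
            histogram_edges=np.array([]),
            per_chromosome_median=pd.Series(dtype=float),
        )
    vals = d["distance"].to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    counts, edges = np.histogram(vals, bins=n_hist_bins)
    return DistanceSummary(
        n_intra=len(vals),
        median=float(q50),
        iqr=float(q75 - q25),
        histogram_counts=counts,
        histogram_edges=edges,
        per_chromosome_median=d.groupby("chrom_a")["distance"].median(),
    )


# ---------------------------------------------------------------------------
# Subsample robustness

def subsample_robustness(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    sizes: list[int],
    n_reps: int = 7,
    fraction: float = 1e-4,
    estimator: str = "binning",
    seed: int = 0,
) -> pd.DataFrame:
    """Re-infer the network on random sample subsets of decreasing size.

    For every size, ``n_reps`` column subsets are drawn without replacement;
    MI estimation, top-fraction thresholding and edge classification are
    rerun on each. Returns one row per (size, rep) with the inter-chromosomal
    fraction, component counts/sizes and the sampled column list (logged for
    reproducibility).
    """
    n_avail = expr.shape[1]
    for size in sizes:
        if size > n_avail:
            raise TopologyError(f"subsample size {size} exceeds available samples {n_avail}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    rows = []
    for size in sizes:
        for rep in range(n_reps):
            cols = expr.columns[rng.choice(n_avail, size=size, replace=False)]
            sub = expr[cols]
            mi = estimate_mi(sub, estimator=estimator, seed=seed)
            net = threshold_top_fraction(mi, fraction)
            ec = classify_edges(net, ann)
            summ = topology_summary(net)
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "inter_fraction": ec.inter_fraction,
                    "n_edges": summ.n_edges,
                    "n_components": summ.n_components,
                    "largest_component": summ.largest_component,
                    "mean_component_size": summ.n_nodes / summ.n_components,
                    "mi_cutoff": net.graph["mi_cutoff"],
                    "samples": ";".join(cols),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contact-table concordance

@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # gene_a, gene_b, mi, frequency, covered
    spearman_rho: float
    spearman_p: float
    correlation_defined: bool
    top_edges: pd.DataFrame


def contact_concordance(
    net: nx.Graph,
    contacts: pd.DataFrame,
    ann: pd.DataFrame,
    top_k: int = 10,
) -> ConcordanceResult:
    """Score network edges against an external contact-frequency table.

    ``contacts`` columns: chr_a, pos_a, chr_b, pos_b, frequency. Each edge is
    matched to the contact entry on its (unordered) chromosome pair whose
    positions are nearest to the two gene midpoints (nearest-bin convention);
    edges with no entry for their chromosome pair are flagged uncovered.
    Reports the Spearman rank correlation between MI and contact frequency
    over covered edges (undefined — and flagged so — when either side is
    constant) and a top-``top_k``-by-MI listing.
    """
    a = ann.drop_duplicates("gene_id").set_index("gene_id")
    chrom = a["chromosome"].astype(str)
    mid = (a["start"] + a["end"]) / 2.0

    ca, cb = contacts["chr_a"].astype(str), contacts["chr_b"].astype(str)
    keep = ca <= cb
    c = pd.DataFrame(
        {
            "chr_a": ca.where(keep, cb),
            "pos_a": contacts["pos_a"].where(keep, contacts["pos_b"]),
            "chr_b": cb.where(keep, ca),
            "pos_b": contacts["pos_b"].where(keep, contacts["pos_a"]),
            "frequency": contacts["frequency"],
        }
    )
    by_pair = {k: v for k, v in c.groupby(["chr_a", "chr_b"])}

    rows = []
    for u, v, d in net.edges(data=True):
        cu, cv, mu, mv = chrom[u], chrom[v], mid[u], mid[v]
        if (cu, mu) > (cv, mv):
            u, v, cu, cv, mu, mv = v, u, cv, cu, mv, mu
        key = (cu, cv) if cu <= cv else (cv, cu)
        grp = by_pair.get(key)
        freq, covered = np.nan, False
        if grp is not None:
            pa, pb = (mu, mv) if cu <= cv else (mv, mu)
            cost = (grp["pos_a"] - pa).abs() + (grp["pos_b"] - pb).abs()
            freq = float(grp.loc[cost.idxmin(), "frequency"])
            covered = True
        rows.append((u, v, d.get("mi", np.nan), freq, covered))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "frequency", "covered"])
    cov = table[table["covered"]]
    if cov.empty:
        raise TopologyError("no network edge overlaps the contact table")
    if cov["frequency"].nunique() <= 1 or cov["mi"].nunique() <= 1:
        rho, p, defined = float("nan"), float("nan"), False
    else:
        rho, p = stats.spearmanr(cov["mi"], cov["frequency"])
        rho, p, defined = float(rho), float(p), True
    top = table.sort_values("mi", ascending=False).head(top_k).reset_index(drop=True)
    return ConcordanceResult(
        table=table,
        spearman_rho=rho,
        spearman_p=p,
        correlation_defined=defined,
        top_edges=top,
    )


# ---------------------------------------------------------------------------
# Export

def write_topology_summary(summ: TopologySummary, path) -> None:
    pd.DataFrame([summ.to_dict()]).to_csv(path, sep="\t", index=False)


def write_degree_table(net: nx.Graph, path) -> None:
    """Per-node degree table, highest degree first."""
    rows = sorted(net.degree, key=lambda t: (-t[1], t[0]))
    pd.DataFrame(rows, columns=["gene_id", "degree"]).to_csv(path, sep="\t", index=False)


def write_circos_links(ec: EdgeClassification, ann: pd.DataFrame, path) -> None:
    """Circos link file: chr, start, end, chr, start, end, weight (MI)."""
    a = ann.drop_duplicates("gene_id").set_index("gene_id")
    with open(path, "w") as f:
        for _, r in ec.edges.iterrows():
            ga, gb = a.loc[r["gene_a"]], a.loc[r["gene_b"]]
            f.write(
                f"{ga['chromosome']}\t{ga['start']}\t{ga['end']}\t"
                f"{gb['chromosome']}\t{gb['start']}\t{gb['end']}\t{r['mi']:.6g}\n"
            )
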