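"""Edge classification, topology metrics, component profiles, robustness."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chromonet import (
    SimulationConfig,
    TopologyError,
    classify_edges,
    component_profiles,
    contact_concordance,
    estimate_mi,
    intra_distance_profile,
    make_annotation,
    simulate_counts,
    subsample_robustness,
    threshold_top_fraction,
    topology_summary,
)


def _ann(genes, chroms, starts=None):
    starts = starts or [1000 * (i + 1) for i in range(len(genes))]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "symbol": genes,
            "alt_symbol": genes,
            "chromosome": chroms,
            "start": starts,
            "end": [s + 99 for s in starts],
            "gc": 0.5,
            "biotype": "protein_coding",
        }
    )


def _net(edges):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, mi=0.5)
    return g


# ---------------------------------------------------------------- classification

def test_classify_intra_and_inter():
    ann = _ann(["a", "b", "c"], ["19", "19", "1"])
    ec = classify_edges(_net([("a", "b"), ("a", "c")]), ann)
    table = ec.edges.set_index(["gene_a", "gene_b"])
    assert table.loc[("a", "b"), "label"] == "intra"
    assert table.loc[("a", "c"), "label"] == "inter"
    assert ec.inter_fraction == pytest.approx(0.5)
    assert ec.intra_counts["19"] == 1


def test_classify_unannotated_gene_raises():
    ann = _ann(["a", "b"], ["1", "1"])
    with pytest.raises(TopologyError, match="zzz"):
        classify_edges(_net([("a", "zzz")]), ann)


def test_classify_invariant_under_edge_order():
    ann = _ann(list("abcd"), ["1", "1", "2", "2"])
    e1 = classify_edges(_net([("a", "b"), ("c", "d"), ("b", "c")]), ann)
    e2 = classify_edges(_net([("b", "c"), ("c", "d"), ("a", "b")]), ann)
    pd.testing.assert_frame_equal(e1.edges, e2.edges)


def test_end_to_end_regime_contrast():
    cfg = SimulationConfig(
        n_genes=200, n_chromosomes=5, block_size=10, n_healthy=80, n_cancer=80,
        rho_intra=0.9, rho_inter=0.6, seed=14,
    )
    ann = make_annotation(cfg)
    counts, samples, _ = simulate_counts(cfg, ann)
    sheet = samples.set_index("sample")["condition"]
    logc = np.log2(counts + 1)
    fracs = {}
    for cond in ("healthy", "cancer"):
        mi = estimate_mi(logc[sheet.index[sheet == cond]], "binning")
        net = threshold_top_fraction(mi, 0.01)
        fracs[cond] = classify_edges(net, ann).inter_fraction
    assert fracs["cancer"] < 0.05
    assert fracs["healthy"] > 0.5


# ---------------------------------------------------------------- topology summary

def test_triangle_summary():
    s = topology_summary(_net([("a", "b"), ("b", "c"), ("a", "c")]))
    assert s.n_components == 1
    assert s.diameter == 1
    assert s.density == 1.0
    assert s.clustering_coefficient == 1.0
    assert s.connected_pairs == 3


def test_path_summary():
    s = topology_summary(_net([("a", "b"), ("b", "c")]))
    assert s.diameter == 2
    assert s.connected_pairs == 3
    assert s.avg_shortest_path == pytest.approx(4 / 3)
    assert s.clustering_coefficient == 0.0


def _bruteforce_summary(g):
    """All-pairs BFS oracle, independent of networkx algorithms."""
    nodes = sorted(g.nodes)
    adj = {n: set(g.neighbors(n)) for n in nodes}

    def bfs(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    comps = []
    seen = set()
    for n in nodes:
        if n not in seen:
            comp = set(bfs(n))
            seen |= comp
            comps.append(comp)
    largest = max(comps, key=len)
    dists = {n: bfs(n) for n in nodes}
    diameter = max(dists[u][v] for u in largest for v in dists[u] if v in largest)
    pair_d = [dists[u][v] for u, v in itertools.combinations(nodes, 2) if v in dists[u]]
    tri = 0.0
    for n in nodes:
        k = len(adj[n])
        if k >= 2:
            links = sum(1 for u, v in itertools.combinations(adj[n], 2) if v in adj[u])
            tri += 2 * links / (k * (k - 1))
    N, E = len(nodes), g.number_of_edges()
    return {
        "n_components": len(comps),
        "largest_component": len(largest),
        "diameter": diameter,
        "connected_pairs": len(pair_d),
        "avg_shortest_path": sum(pair_d) / len(pair_d),
        "avg_degree": 2 * E / N,
        "density": 2 * E / (N * (N - 1)),
        "clustering_coefficient": tri / N,
    }


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_summary_matches_bruteforce_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(30, 0.08, seed=seed)
    g.remove_nodes_from(list(nx.isolates(g)))
    s = topology_summary(g).to_dict()
    ref = _bruteforce_summary(g)
    for key, val in ref.items():
        assert s[key] == pytest.approx(val), key


@pytest.mark.parametrize("seed", [4, 5])
def test_component_pairs_sum_to_connected_pairs(seed):
    g = nx.gnp_random_graph(40, 0.05, seed=seed)
    g.remove_nodes_from(list(nx.isolates(g)))
    s = topology_summary(g)
    profs = component_profiles(g)
    assert sum(math.comb(p.size, 2) for p in profs) == s.connected_pairs


# ---------------------------------------------------------------- components

def test_clique_ranked_first_and_sign_homogeneity():
    g = _net([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d"),
              ("w", "x"), ("x", "y"), ("y", "z")])
    for n, lfc in {"a": -1, "b": -2, "c": -0.5, "d": -3,
                   "w": 1, "x": -1, "y": 2, "z": 3}.items():
        g.nodes[n]["log2fc"] = lfc
        g.nodes[n]["chromosome"] = "7" if n in "abcd" else "8"
    profs = component_profiles(g)
    assert profs[0].genes == ("a", "b", "c", "d")
    assert profs[0].density == 1.0
    assert profs[0].de_sign_homogeneity == 1.0  # all underexpressed
    assert profs[0].chromosome_homogeneity == 1.0
    assert profs[1].de_sign_homogeneity == pytest.approx(0.75)


def test_component_tie_break_by_size_then_member():
    g = _net([("a", "b"), ("c", "d"), ("e", "f"), ("f", "g"), ("e", "g")])
    profs = component_profiles(g)
    # triangle (density 1, size 3) before the two edges (density 1, size 2);
    # equal-density equal-size components ordered by smallest member
    assert [p.genes for p in profs] == [("e", "f", "g"), ("a", "b"), ("c", "d")]


def test_synthetic_cancer_components_are_chromosome_pure():
    cfg = SimulationConfig(
        n_genes=200, n_chromosomes=5, block_size=10, n_healthy=20, n_cancer=120,
        rho_intra=0.9, rho_inter=0.0, seed=15,
    )
    ann = make_annotation(cfg)
    counts, samples, _ = simulate_counts(cfg, ann)
    sheet = samples.set_index("sample")["condition"]
    logc = np.log2(counts + 1)
    mi = estimate_mi(logc[sheet.index[sheet == "cancer"]], "binning")
    net = threshold_top_fraction(mi, 0.01)
    profs = component_profiles(net, ann=ann)
    assert np.mean([p.chromosome_homogeneity for p in profs]) >= 0.9


# ---------------------------------------------------------------- distances

def test_intra_distance_values():
    ann = _ann(["a", "b", "c"], ["1", "1", "2"], starts=[1000, 2000, 5000])
    # midpoints 1049.5 and 2049.5 -> distance 1000
    ec = classify_edges(_net([("a", "b"), ("a", "c")]), ann)
    summ = intra_distance_profile(ec)
    assert summ.n_intra == 1
    assert summ.median == pytest.approx(1000.0)
    assert summ.per_chromosome_median["1"] == pytest.approx(1000.0)


def test_intra_distance_empty_summary_not_error():
    ann = _ann(["a", "b"], ["1", "2"])
    ec = classify_edges(_net([("a", "b")]), ann)
    summ = intra_distance_profile(ec)
    assert summ.n_intra == 0 and np.isnan(summ.median)


def test_cancer_neighbourhood_distances_below_chromosome_scale():
    cfg = SimulationConfig(
        n_genes=200, n_chromosomes=4, block_size=10, n_healthy=80, n_cancer=80,
        rho_intra=0.9, rho_inter=0.6, seed=16,
    )
    ann = make_annotation(cfg)
    counts, samples, _ = simulate_counts(cfg, ann)
    sheet = samples.set_index("sample")["condition"]
    logc = np.log2(counts + 1)
    a = ann.set_index("gene_id")
    span = {}
    for cond in ("healthy", "cancer"):
        mi = estimate_mi(logc[sheet.index[sheet == cond]], "binning")
        ec = classify_edges(threshold_top_fraction(mi, 0.01), ann)
        span[cond] = intra_distance_profile(ec).median
    # block span: ~10 consecutive genes; chromosome holds ~50
    chrom_span = (a.groupby("chromosome")["end"].max() - a.groupby("chromosome")["start"].min()).median()
    assert span["cancer"] < 0.35 * chrom_span
    assert span["healthy"] > span["cancer"]


# ---------------------------------------------------------------- subsampling

def test_subsample_full_size_reproduces_network(small_dataset):
    ann, counts, samples, _ = small_dataset
    sheet = samples.set_index("sample")["condition"]
    cancer = sheet.index[sheet == "cancer"]
    logc = np.log2(counts[cancer] + 1)
    res = subsample_robustness(logc, ann, sizes=[len(cancer)], n_reps=1, fraction=0.02, seed=1)
    mi = estimate_mi(logc, "binning", seed=1)
    net = threshold_top_fraction(mi, 0.02)
    assert res.loc[0, "n_edges"] == net.number_of_edges()
    assert res.loc[0, "inter_fraction"] == pytest.approx(
        classify_edges(net, ann).inter_fraction
    )


def test_subsample_size_validation_and_seed_effect(small_dataset):
    ann, counts, samples, _ = small_dataset
    sheet = samples.set_index("sample")["condition"]
    cancer = sheet.index[sheet == "cancer"]
    logc = np.log2(counts[cancer] + 1)
    with pytest.raises(TopologyError):
        subsample_robustness(logc, ann, sizes=[10 * len(cancer)], n_reps=1, seed=0)
    r1 = subsample_robustness(logc, ann, sizes=[25], n_reps=1, fraction=0.02, seed=0)
    r2 = subsample_robustness(logc, ann, sizes=[25], n_reps=1, fraction=0.02, seed=99)
    assert r1.loc[0, "samples"] != r2.loc[0, "samples"]  # memberships logged


def test_subsampled_cancer_networks_stay_intra_chromosomal():
    cfg = SimulationConfig(
        n_genes=150, n_chromosomes=5, block_size=10, n_healthy=20, n_cancer=120,
        rho_intra=0.9, rho_inter=0.0, seed=17,
    )
    ann = make_annotation(cfg)
    counts, samples, _ = simulate_counts(cfg, ann)
    sheet = samples.set_index("sample")["condition"]
    cancer = sheet.index[sheet == "cancer"]
    logc = np.log2(counts[cancer] + 1)
    res = subsample_robustness(
        logc, ann, sizes=[40, 80, 120], n_reps=3, fraction=0.01, seed=2
    )
    assert (res["inter_fraction"] < 0.1).all()


# ---------------------------------------------------------------- contact table

def test_contact_concordance_perfect_and_degenerate():
    ann = _ann(list("abcd"), ["1", "1", "2", "2"])
    net = _net([("a", "b"), ("a", "c"), ("b", "d")])
    for (u, v), w in zip([("a", "b"), ("a", "c"), ("b", "d")], [0.9, 0.5, 0.1]):
        net[u][v]["mi"] = w
    a = ann.set_index("gene_id")
    rows = []
    for u, v in net.edges:
        rows.append(
            {
                "chr_a": a.at[u, "chromosome"], "pos_a": a.at[u, "start"],
                "chr_b": a.at[v, "chromosome"], "pos_b": a.at[v, "start"],
                "frequency": net[u][v]["mi"] * 100,  # same ranking as MI
            }
        )
    res = contact_concordance(net, pd.DataFrame(rows), ann)
    assert res.correlation_defined
    assert res.spearman_rho == pytest.approx(1.0)
    const = pd.DataFrame(rows).assign(frequency=7.0)
    res2 = contact_concordance(net, const, ann)
    assert not res2.correlation_defined and np.isnan(res2.spearman_rho)


def test_contact_concordance_matches_bruteforce_spearman():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(11)]
    ann = _ann(genes, ["1"] * 6 + ["2"] * 5)
    edges = [(genes[i], genes[i + 1]) for i in range(10)]
    net = _net(edges)
    mis = rng.random(10)
    freqs = rng.random(10)
    a = ann.set_index("gene_id")
    rows = []
    for (u, v), m, f in zip(edges, mis, freqs):
        net[u][v]["mi"] = m
        rows.append({"chr_a": a.at[u, "chromosome"], "pos_a": (a.at[u, "start"] + a.at[u, "end"]) / 2,
                     "chr_b": a.at[v, "chromosome"], "pos_b": (a.at[v, "start"] + a.at[v, "end"]) / 2,
                     "frequency": f})
    res = contact_concordance(net, pd.DataFrame(rows), ann)

    def ranks(x):
        order = sorted(range(len(x)), key=lambda i: x[i])
        r = [0.0] * len(x)
        for pos, i in enumerate(order):
            r[i] = pos + 1
        return r

    tab = res.table
    rx, ry = ranks(list(tab["mi"])), ranks(list(tab["frequency"]))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((x - mx) * (y - my) for x, y in zip(rx, ry))
    den = math.sqrt(sum((x - mx) ** 2 for x in rx) * sum((y - my) ** 2 for y in ry))
    assert res.spearman_rho == pytest.approx(num / den, abs=1e-12)


def test_contact_concordance_uncovered_edges_flagged():
    ann = _ann(list("abc"), ["1", "1", "3"])
    net = _net([("a", "b"), ("a", "c")])
    contacts = pd.DataFrame(
        [{"chr_a": "1", "pos_a": 1000, "chr_b": "1", "pos_b": 2000, "frequency": 5.0}]
    )
    res = contact_concordance(net, contacts, ann)
    tab = res.table.set_index(["gene_a", "gene_b"])
    assert bool(tab.loc[("a", "b"), "covered"])
    assert not bool(tab.loc[("a", "c"), "covered"])
    with pytest.raises(TopologyError):
        contact_concordance(_net([("a", "c")]), contacts, ann)
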