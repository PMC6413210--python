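"""Thresholded co-occurrence graph, fast-greedy module separation, and
network summary/comparison statistics.

Modules are found by agglomerative greedy modularity maximization
(Clauset-Newman-Moore style): start from singleton modules and repeatedly
apply the merge with the largest modularity gain until no merge improves Q.
Tie-breaking and label ordering are deterministic so runs are reproducible.
Modularity is computed on the unweighted graph by default; edge sign is
annotation only (negative associations still count as edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .rmt import SimilarityMatrix


@dataclass
class Partition:
    """Module label per node (1-based contiguous integers) and modularity Q."""

    labels: dict[str, int]
    q: float

    def __post_init__(self) -> None:
        mods = sorted(set(self.labels.values()))
        if mods and mods != list(range(1, len(mods) + 1)):
            raise ValueError("module labels must be contiguous 1-based integers")

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def members(self, module: int) -> set[str]:
        return {n for n, m in self.labels.items() if m == module}


def build_network(sim: SimilarityMatrix, threshold: float) -> nx.Graph:
    """Edges where |r| >= threshold; weight = |r|, sign from the signed
    matrix; isolated nodes are dropped."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    g = nx.Graph()
    r = sim.signed
    n = len(sim.otu_ids)
    ii, jj = np.where(np.triu(np.abs(r), k=1) >= threshold)
    for i, j in zip(ii, jj):
        g.add_edge(sim.otu_ids[i], sim.otu_ids[j],
                   weight=float(abs(r[i, j])),
                   sign="+" if r[i, j] >= 0 else "-")
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges survive threshold {threshold}")
    return g


def modularity(net: nx.Graph, labels: dict[str, int], weighted: bool = False) -> float:
    """Newman modularity Q = sum_m (e_mm - a_m^2).

    e_mm is the fraction of edge weight inside module m and a_m the fraction
    of edge endpoints attached to m. Unweighted by default.
    """
    missing = [n for n in net.nodes if n not in labels]
    if missing:
        raise ValueError(f"nodes without a module label: {sorted(missing)[:5]}")
    mods = sorted(set(labels[n] for n in net.nodes))
    idx = {m: k for k, m in enumerate(mods)}
    e = np.zeros(len(mods))
    a = np.zeros(len(mods))
    total = 0.0
    for u, v, d in net.edges(data=True):
        w = float(d.get("weight", 1.0)) if weighted else 1.0
        total += w
        mu, mv = idx[labels[u]], idx[labels[v]]
        if mu == mv:
            e[mu] += w
        a[mu] += w
        a[mv] += w
    if total == 0:
        return 0.0
    return float(np.sum(e / total - (a / (2.0 * total)) ** 2))


def _relabel_canonical(groups: list[set[str]]) -> dict[str, int]:
    """1-based labels ordered by descending module size, then smallest member id."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {n: k + 1 for k, grp in enumerate(ordered) for n in grp}


def fast_greedy_modules(net: nx.Graph, weighted: bool = False) -> Partition:
    """Agglomerative greedy modularity optimization.

    Starts with singleton modules, repeatedly merges the connected pair of
    modules with the largest Q gain (ties broken by the smallest
    (module, module) index pair), and stops when no merge increases Q.
    Connected components are processed independently.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes, key=str)
    node_idx = {n: i for i, n in enumerate(nodes)}
    m = net.number_of_edges()
    if m == 0:
        return Partition({n: i + 1 for i, n in enumerate(nodes)}, 0.0)

    def w_of(d):
        return float(d.get("weight", 1.0)) if weighted else 1.0

    total = sum(w_of(d) for _, _, d in net.edges(data=True))
    # community state: comm id -> member node indices; e[(i,j)] inter-community weight
    comm: dict[int, set[int]] = {i: {i} for i in range(len(nodes))}
    a = np.zeros(len(nodes))
    inter: dict[tuple[int, int], float] = {}
    intra = np.zeros(len(nodes))
    for u, v, d in net.edges(data=True):
        w = w_of(d)
        iu, iv = node_idx[u], node_idx[v]
        a[iu] += w
        a[iv] += w
        if iu == iv:
            continue
        key = (min(iu, iv), max(iu, iv))
        inter[key] = inter.get(key, 0.0) + w

    two_m = 2.0 * total
    while True:
        # merge gain: dQ = 2 * (e_ij/2m - a_i a_j / (2m)^2) in the e/a bookkeeping
        best = None
        for (i, j), eij in inter.items():
            dq = 2.0 * (eij / two_m - (a[i] / two_m) * (a[j] / two_m))
            if best is None or dq > best[0] + 1e-15 or (
                    abs(dq - best[0]) <= 1e-15 and (i, j) < best[1]):
                best = (dq, (i, j))
        if best is None or best[0] <= 1e-15:
            break
        dq, (i, j) = best
        # merge j into i
        comm[i] |= comm.pop(j)
        intra[i] += intra[j] + inter.pop((i, j))
        a[i] += a[j]
        for (p, q_), w in list(inter.items()):
            if j in (p, q_):
                other = q_ if p == j else p
                del inter[(p, q_)]
                key = (min(i, other), max(i, other))
                inter[key] = inter.get(key, 0.0) + w

    groups = [{nodes[i] for i in members} for members in comm.values()]
    labels = _relabel_canonical(groups)
    return Partition(labels, modularity(net, labels, weighted=weighted))


def network_summary(net: nx.Graph, partition: Partition | None = None) -> dict:
    """Global topology statistics of the co-occurrence network."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = net.number_of_edges()
    # average shortest path over connected pairs only
    tot_len = 0
    n_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        tot_len += sum(dists.values())
        n_pairs += len(dists) - 1
    summary = {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2.0 * e / n,
        "density": nx.density(net),
        "avg_clustering": nx.average_clustering(net),
        "avg_path_length": tot_len / n_pairs if n_pairs else float("nan"),
    }
    if partition is not None:
        summary["n_modules"] = partition.n_modules
        summary["modularity"] = partition.q
    return summary


def module_overlap(p_a: Partition, p_b: Partition) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-member contingency and per-pair Jaccard between two partitions.

    Partitions may cover different node sets; overlap is computed on the
    intersection. Returns (counts, jaccard) DataFrames indexed by module in
    A, columns = module in B.
    """
    nodes_a, nodes_b = set(p_a.labels), set(p_b.labels)
    common = nodes_a & nodes_b
    if not common:
        raise ValueError("partitions share no nodes")
    mods_a = sorted(set(p_a.labels.values()))
    mods_b = sorted(set(p_b.labels.values()))
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b)
    for n in common:
        counts.loc[p_a.labels[n], p_b.labels[n]] += 1
    jac = pd.DataFrame(0.0, index=mods_a, columns=mods_b)
    for ma in mods_a:
        set_a = p_a.members(ma)
        for mb in mods_b:
            set_b = p_b.members(mb)
            union = len(set_a | set_b)
            jac.loc[ma, mb] = len(set_a & set_b) / union if union else 0.0
    counts.index.name = jac.index.name = "module_a"
    counts.columns.name = jac.columns.name = "module_b"
    return counts, jac
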