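"""Within-module degree (Zi), participation coefficient (Pi), and node
topological roles.

Zi is the z-score of a node's link count into its own module relative to
its module peers (population standard deviation); Pi = 1 - sum over modules
of the squared fraction of the node's links landing in each module. Roles
follow the four-quadrant classification at Zi = 2.5 and Pi = 0.62:
peripheral, connector, module hub, network hub. Values exactly at a cutoff
fall on the hub/connector side, making the four regions exhaustive.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import Partition

Z_CUT = 2.5
P_CUT = 0.62


def _module_link_counts(net: nx.Graph, partition: Partition) -> dict[str, dict[int, int]]:
    """node -> {module: number of links into that module}."""
    missing = [n for n in net.nodes if n not in partition.labels]
    if missing:
        raise ValueError(f"nodes without a module label: {sorted(missing)[:5]}")
    out: dict[str, dict[int, int]] = {n: {} for n in net.nodes}
    for u, v in net.edges:
        out[u][partition.labels[v]] = out[u].get(partition.labels[v], 0) + 1
        out[v][partition.labels[u]] = out[v].get(partition.labels[u], 0) + 1
    return out


def within_module_degree(net: nx.Graph, partition: Partition) -> pd.Series:
    """Zi per node; 0 where a module's within-degrees have zero spread."""
    links = _module_link_counts(net, partition)
    kw = {n: links[n].get(partition.labels[n], 0) for n in net.nodes}
    zi = {}
    for m in sorted(set(partition.labels[n] for n in net.nodes)):
        members = [n for n in net.nodes if partition.labels[n] == m]
        vals = np.array([kw[n] for n in members], dtype=float)
        mean, sd = vals.mean(), vals.std()  # population sd
        for n in members:
            zi[n] = (kw[n] - mean) / sd if sd > 0 else 0.0
    return pd.Series(zi, name="Zi").sort_index()


def participation_coefficient(net: nx.Graph, partition: Partition) -> pd.Series:
    """Pi per node. Isolated nodes are rejected (the builder drops them)."""
    links = _module_link_counts(net, partition)
    pi = {}
    for n in net.nodes:
        k = sum(links[n].values())
        if k == 0:
            raise ValueError(f"node {n!r} is isolated; Pi is undefined")
        pi[n] = 1.0 - sum((kt / k) ** 2 for kt in links[n].values())
    return pd.Series(pi, name="Pi").sort_index()


def classify_roles(zi: pd.Series, pi: pd.Series,
                   z_cut: float = Z_CUT, p_cut: float = P_CUT) -> pd.Series:
    """Four-quadrant role per node from (Zi, Pi)."""
    roles = {}
    for n in zi.index:
        z, p = zi[n], pi[n]
        if not (np.isfinite(z) and np.isfinite(p)):
            raise ValueError(f"non-finite Zi/Pi for node {n!r}")
        if z >= z_cut:
            roles[n] = "network hub" if p >= p_cut else "module hub"
        else:
            roles[n] = "connector" if p >= p_cut else "peripheral"
    return pd.Series(roles, name="role").sort_index()


def node_topology(net: nx.Graph, partition: Partition,
                  z_cut: float = Z_CUT, p_cut: float = P_CUT,
                  phylum_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-node table: degree, module, Zi, Pi, role (and phylum if given)."""
    zi = within_module_degree(net, partition)
    pi = participation_coefficient(net, partition)
    roles = classify_roles(zi, pi, z_cut=z_cut, p_cut=p_cut)
    df = pd.DataFrame({
        "node": zi.index,
        "degree": [net.degree[n] for n in zi.index],
        "module": [partition.labels[n] for n in zi.index],
        "Zi": zi.values,
        "Pi": pi.values,
        "role": roles.values,
    })
    if phylum_of is not None:
        df["phylum"] = [phylum_of.get(n, "") for n in df["node"]]
    return df
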