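"""Readers and writers for the tabular and graph artifacts of the pipeline.

Supported formats: OTU-table TSV (first column = OTU id, optional trailing
``taxonomy`` column), BIOM v1 JSON, trait-table CSV (``sample_id,group,trait``),
GraphML with node/edge annotations, and a Cytoscape-compatible edge-list TSV.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_GG_PREFIX = re.compile(r"^[kpcofgs]__")


@dataclass(frozen=True)
class Taxonomy:
    """A seven-rank taxonomy lineage; unassigned ranks are empty strings.

    Once a rank is empty every lower rank is empty as well.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        ranks = self.as_tuple()
        seen_empty = False
        for r in ranks:
            if r == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"rank gap in lineage {ranks!r}: a filled rank follows an empty one")

    def as_tuple(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    def rank(self, name: str) -> str:
        name = "class_" if name == "class" else name
        if name not in self.__dataclass_fields__:
            raise KeyError(f"unknown taxonomy rank {name!r}")
        return getattr(self, name)


def parse_lineage(text: str) -> Taxonomy:
    """Parse a taxonomy lineage string into a :class:`Taxonomy`.

    Accepts both pipe-separated lineages (``Bacteria|Firmicutes|Clostridia``)
    and Greengenes-style strings (``k__Bacteria; p__Firmicutes; ...``).
    Missing ranks come back empty; unparseable text yields an all-empty
    lineage with a logged warning rather than an error.
    """
    if text is None:
        return Taxonomy()
    text = text.strip().strip('"')
    if not text:
        return Taxonomy()
    sep = "|" if "|" in text else ";"
    parts = [p.strip() for p in text.split(sep)]
    names: list[str] = []
    for p in parts:
        p = _GG_PREFIX.sub("", p).strip().strip("*").strip()
        names.append(p)
    # truncate at first empty rank; anything after it would violate the gap rule
    filled: list[str] = []
    for n in names[: len(RANKS)]:
        if n == "":
            break
        filled.append(n)
    if not filled:
        logger.warning("unparseable lineage %r; treating as unassigned", text)
        return Taxonomy()
    filled += [""] * (len(RANKS) - len(filled))
    return Taxonomy(*filled)


@dataclass
class OtuTable:
    """Non-negative OTU count matrix (rows = OTUs, columns = samples).

    ``lineages`` carries one taxonomy string per OTU and may be all-empty.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not self.lineages:
            self.lineages = [""] * len(self.otu_ids)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples")
        if len(self.lineages) != len(self.otu_ids):
            raise ValueError("one lineage required per OTU")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = pd.Index(self.otu_ids)
            raise ValueError(f"duplicated OTU ids: {sorted(dupes[dupes.duplicated()])}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            raise ValueError(f"duplicated sample ids: {sorted(dupes[dupes.duplicated()])}")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def taxonomies(self) -> list[Taxonomy]:
        return [parse_lineage(t) for t in self.lineages]

    def select_otus(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            otu_ids=[self.otu_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep, :].copy(),
            lineages=[self.lineages[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class TraitTable:
    """One numeric trait value per sample, with optional group labels."""

    sample_ids: list[str]
    values: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.sample_ids):
            raise ValueError("one trait value required per sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample id in trait table")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label required per sample")

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Trait values reordered to match ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples missing from trait table: {missing}")
        return self.values[[pos[s] for s in sample_ids]]


# ---------------------------------------------------------------------------
# OTU table I/O


def _read_otu_tsv(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    if df.index.name is None and df.empty:
        raise ValueError(f"{path}: empty or malformed header")
    cols = list(df.columns)
    lineages: list[str] = []
    if cols and cols[-1].strip().lower() == "taxonomy":
        lineages = df[cols[-1]].fillna("").tolist()
        df = df.drop(columns=cols[-1])
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, c in enumerate(df.columns):
        for i, v in enumerate(df[c]):
            try:
                x = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric count {v!r} at OTU {otu_ids[i]!r}, sample {c!r}")
            if x < 0:
                raise ValueError(f"{path}: negative count at OTU {otu_ids[i]!r}, sample {c!r}")
            if x != int(x):
                raise ValueError(f"{path}: non-integer count {v!r} at OTU {otu_ids[i]!r}, sample {c!r}")
            counts[i, j] = int(x)
    return OtuTable(otu_ids, sample_ids, counts, lineages)


def _read_otu_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format", "").startswith("Biological Observation Matrix 2"):
        raise ValueError(f"{path}: BIOM 2.x (HDF5) is not supported; export v1 JSON")
    shape = doc["shape"]
    n_otus, n_samples = int(shape[0]), int(shape[1])
    otu_ids, lineages = [], []
    for row in doc["rows"]:
        otu_ids.append(str(row["id"]))
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy", "")
        if isinstance(tax, list):
            tax = "; ".join(str(t) for t in tax)
        lineages.append(str(tax) if tax else "")
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    data = doc["data"]
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = int(v)
    else:
        counts[:, :] = np.asarray(data, dtype=np.int64)
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(f"{path}: negative count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}")
    return OtuTable(otu_ids, sample_ids, counts, lineages)


def read_otu_table(path: str | Path, dialect: str = "tsv") -> OtuTable:
    """Read an OTU count table from ``path``.

    Parameters
    ----------
    dialect
        ``"tsv"`` (first column = OTU id, optional trailing ``taxonomy``
        column) or ``"biom-json"`` (BIOM v1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "tsv":
        return _read_otu_tsv(path)
    if dialect == "biom-json":
        return _read_otu_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'biom-json'")


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``table`` in the named dialect (inverse of :func:`read_otu_table`)."""
    path = Path(path)
    if dialect == "tsv":
        df = table.to_frame()
        if any(table.lineages):
            df = df.copy()
            df["taxonomy"] = table.lineages
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")
        return
    if dialect == "biom-json":
        rows = []
        for oid, lin in zip(table.otu_ids, table.lineages):
            meta = {"taxonomy": lin} if lin else None
            rows.append({"id": oid, "metadata": meta})
        data = [[int(i), int(j), int(v)]
                for (i, j), v in np.ndenumerate(table.counts) if v != 0]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "micronet",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Trait table I/O


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a ``sample_id,group,trait`` CSV (group column optional)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "trait" not in cols:
        raise ValueError(f"{path}: expected columns sample_id[,group],trait")
    groups = df[cols["group"]].astype(str).tolist() if "group" in cols else None
    return TraitTable(
        sample_ids=df[cols["sample_id"]].astype(str).tolist(),
        values=df[cols["trait"]].to_numpy(dtype=float),
        groups=groups,
    )


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": traits.sample_ids})
    df["group"] = traits.groups if traits.groups is not None else ""
    df["trait"] = traits.values
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Graph export


def write_network_graphml(network: nx.Graph, topology: pd.DataFrame,
                          partition: dict[str, int], path: str | Path) -> None:
    """Export the network as GraphML with per-node and per-edge annotations.

    Node attributes: ``module``, ``Zi``, ``Pi``, ``role``, ``phylum``.
    Edge attributes: ``weight`` (|r|) and ``sign`` ("+" cooperative,
    "-" competitive).
    """
    g = nx.Graph()
    topo = topology.set_index("node") if "node" in topology.columns else topology
    for n in network.nodes:
        if n not in partition:
            raise ValueError(f"node {n!r} missing a module label")
        if n not in topo.index:
            raise ValueError(f"node {n!r} missing topology attributes")
        row = topo.loc[n]
        g.add_node(n, module=int(partition[n]), Zi=float(row["Zi"]),
                   Pi=float(row["Pi"]), role=str(row["role"]),
                   phylum=str(row.get("phylum", "")))
    for u, v, d in network.edges(data=True):
        g.add_edge(u, v, weight=float(d["weight"]), sign=str(d["sign"]))
    nx.write_graphml(g, str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write a Cytoscape-importable TSV edge list.

    Undirected edges are canonicalized (source < target lexicographically)
    and sorted, so the file is byte-identical regardless of insertion order.
    """
    rows = []
    for u, v, d in network.edges(data=True):
        a, b = (u, v) if str(u) < str(v) else (v, u)
        rows.append((str(a), str(b), float(d["weight"]), str(d["sign"])))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsign\n")
        for a, b, w, s in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\t{s}\n")
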