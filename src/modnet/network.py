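"""Regulatory-network assembly, degree-based modulator filtering, comparison.

Retained triplets become a bipartite modulator -> target edge set around a
single TF hub.  Because most modulators pick up a handful of targets by
chance, modulators are filtered against a connection-shuffle null: the
observed number of edges is redistributed uniformly at random over all
(modulator, target) pairs (no multi-edges), the pooled per-modulator degree
distribution over many shuffles gives a degree threshold at a chosen
quantile, and only modulators at or above it survive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .classes import CLASS_LABELS, modulator_involving_classes
from .triplets import TripletFit

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """TF-centred bipartite network of modulator -> target edges.

    ``edges`` maps each (modulator, target) pair to the set of behaviour
    classes its triplets fell into (several classes can support the same
    pair when fits from different scans are merged).  TF-target and
    modulator-TF links are implied by the hub topology and materialized
    only on export.
    """

    tf_id: str
    edges: dict[tuple[str, str], frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (m, t) in self.edges:
            if m == t or m == self.tf_id or t == self.tf_id:
                raise ValueError(f"self/TF edge not allowed: ({m}, {t})")

    @property
    def modulator_nodes(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def target_nodes(self) -> set[str]:
        return {t for _, t in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, modulator: str) -> int:
        """Number of distinct targets connected to a modulator."""
        return sum(1 for (m, _) in self.edges if m == modulator)

    def degrees(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m, _ in self.edges:
            out[m] = out.get(m, 0) + 1
        return out


@dataclass
class DegreeNull:
    """Shuffle-based null for modulator degree.

    ``threshold`` is the ceiling of the chosen quantile of the pooled
    per-modulator degree distribution over all shuffles (modulators left
    with zero targets in a shuffle contribute zeros).  ``expected_passers``
    is the mean number of modulators per shuffle at or above the
    threshold, the numerator of an FDR-style ratio against the observed
    passers.
    """

    n_shuffles: int
    quantile: float
    threshold: int
    null_degrees: np.ndarray  # pooled, length n_shuffles * |modulators|
    expected_passers: float


def build_network(
    fits,
    tf_id: str | None = None,
    keep_classes: frozenset[int] | None = None,
    max_p_filter: float | None = None,
) -> RegulatoryNetwork:
    """Assemble a network from classified triplet fits.

    Only fits whose class is in ``keep_classes`` (default: the 22
    modulator-involving classes) contribute edges; ``max_p_filter``
    additionally requires the interaction p-value below the given bound.
    Duplicate (modulator, target) pairs collapse into one edge carrying
    all class annotations.
    """
    if keep_classes is None:
        keep_classes = modulator_involving_classes()
    fits = list(fits)
    if tf_id is None:
        if not fits:
            raise ValueError("cannot infer tf_id from an empty fit list")
        tf_id = fits[0].tf_id
    edges: dict[tuple[str, str], set[int]] = {}
    for f in fits:
        if f.class_index is None:
            raise ValueError(f"unclassified fit ({f.modulator_id}, {f.target_id})")
        if f.class_index not in keep_classes:
            continue
        if max_p_filter is not None and f.p_b2 >= max_p_filter:
            continue
        edges.setdefault((f.modulator_id, f.target_id), set()).add(f.class_index)
    if not edges:
        logger.warning("no triplets retained; network is empty")
    return RegulatoryNetwork(
        tf_id=tf_id, edges={k: frozenset(v) for k, v in edges.items()}
    )


def degree_null(
    net: RegulatoryNetwork,
    n_shuffles: int = 1000,
    quantile: float = 0.95,
    seed: int | None = None,
) -> DegreeNull:
    """Shuffle the network's connections and pool null modulator degrees.

    Each shuffle reassigns all edges uniformly at random over the
    |M| x |T| grid without duplicate pairs, keeping node sets and edge
    count fixed.  The degree threshold is the ceiling of the pooled
    empirical quantile.
    """
    mods = sorted(net.modulator_nodes)
    tgts = sorted(net.target_nodes)
    n_m, n_t, n_e = len(mods), len(tgts), net.n_edges
    if n_e < 1:
        raise ValueError("network has no edges")
    if n_e > n_m * n_t:
        raise ValueError(
            f"{n_e} edges cannot be placed on {n_m}x{n_t} pairs without duplicates"
        )
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_shuffles, n_m), dtype=np.int64)
    for s in range(n_shuffles):
        pair_idx = rng.choice(n_m * n_t, size=n_e, replace=False)
        deg = np.bincount(pair_idx // n_t, minlength=n_m)
        assert deg.sum() == n_e  # shuffles conserve edge count
        pooled[s] = deg
    flat = pooled.ravel()
    threshold = int(math.ceil(float(np.quantile(flat, quantile))))
    expected_passers = float((pooled >= threshold).sum(axis=1).mean())
    return DegreeNull(
        n_shuffles=n_shuffles,
        quantile=quantile,
        threshold=threshold,
        null_degrees=flat,
        expected_passers=expected_passers,
    )


def filter_modulators(
    net: RegulatoryNetwork, null: DegreeNull
) -> RegulatoryNetwork:
    """Keep modulators whose degree reaches the null threshold.

    Retains modulators with observed degree >= ``null.threshold`` and
    their incident edges; targets orphaned by the filter drop out with
    them.  The number of null passers expected per shuffle is logged as
    an FDR-style ratio against the observed passers.
    """
    degs = net.degrees()
    keep = {m for m, d in degs.items() if d >= null.threshold}
    if not keep:
        logger.warning("no modulator reaches degree threshold %d", null.threshold)
    if keep:
        ratio = null.expected_passers / len(keep)
        logger.info(
            "degree threshold %d: %d/%d modulators kept (null expectation %.2f, "
            "FDR-style ratio %.3f)",
            null.threshold, len(keep), len(degs), null.expected_passers, ratio,
        )
    edges = {(m, t): c for (m, t), c in net.edges.items() if m in keep}
    return RegulatoryNetwork(tf_id=net.tf_id, edges=edges)


def compare_networks(net_a: RegulatoryNetwork, net_b: RegulatoryNetwork) -> dict:
    """Overlap of (modulator, target) pairs between two networks.

    ``net_a`` is the reference: the reported fraction is |overlap| / |A|.
    Both networks must concern the same TF.
    """
    if net_a.tf_id != net_b.tf_id:
        raise ValueError(
            f"networks have different TFs: {net_a.tf_id!r} vs {net_b.tf_id!r}"
        )
    overlap = set(net_a.edges) & set(net_b.edges)
    n_a = net_a.n_edges
    return {
        "tf": net_a.tf_id,
        "n_overlap": len(overlap),
        "n_a": n_a,
        "n_b": net_b.n_edges,
        "fraction": (len(overlap) / n_a) if n_a else 0.0,
        "overlap_pairs": sorted(overlap),
    }


def export_network(
    net: RegulatoryNetwork,
    path: str | Path,
    fmt: str = "tsv",
    header_comment: str | None = None,
) -> None:
    """Write the network as an edge-list TSV or GraphML file.

    TSV columns: modulator, target, class_index, class_label — one row per
    (edge, class annotation).  GraphML carries node roles and the class
    set per edge; both formats round-trip losslessly through
    :func:`load_network`.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# tf={net.tf_id}\n")
            fh.write("modulator\ttarget\tclass_index\tclass_label\n")
            for (m, t) in sorted(net.edges):
                for c in sorted(net.edges[(m, t)]):
                    fh.write(f"{m}\t{t}\t{c}\t{CLASS_LABELS[c]}\n")
    elif fmt == "graphml":
        g = nx.DiGraph(tf=net.tf_id)
        g.add_node(f"TF:{net.tf_id}", role="tf", gene=net.tf_id)
        for m in sorted(net.modulator_nodes):
            g.add_node(f"M:{m}", role="modulator", gene=m)
            g.add_edge(f"M:{m}", f"TF:{net.tf_id}", kind="modulates")
        for t in sorted(net.target_nodes):
            g.add_node(f"T:{t}", role="target", gene=t)
            g.add_edge(f"TF:{net.tf_id}", f"T:{t}", kind="regulates")
        for (m, t), classes in sorted(net.edges.items()):
            g.add_edge(
                f"M:{m}", f"T:{t}", kind="triplet",
                classes=",".join(str(c) for c in sorted(classes)),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'tsv' or 'graphml'")


def load_network(path: str | Path, fmt: str = "tsv") -> RegulatoryNetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "tsv":
        tf_id = None
        edges: dict[tuple[str, str], set[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\r\n")
                if line.startswith("# tf="):
                    tf_id = line[len("# tf="):]
                    continue
                if not line or line.startswith("#") or line.startswith("modulator\t"):
                    continue
                m, t, c, _label = line.split("\t")
                edges.setdefault((m, t), set()).add(int(c))
        if tf_id is None:
            raise ValueError(f"{path}: missing '# tf=' header")
        return RegulatoryNetwork(
            tf_id=tf_id, edges={k: frozenset(v) for k, v in edges.items()}
        )
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        tf_id = g.graph["tf"]
        edges = {}
        for u, v, data in g.edges(data=True):
            if data.get("kind") != "triplet":
                continue
            m = g.nodes[u]["gene"]
            t = g.nodes[v]["gene"]
            classes = frozenset(int(c) for c in data["classes"].split(","))
            edges[(m, t)] = classes
        return RegulatoryNetwork(tf_id=tf_id, edges=edges)
    raise ValueError(f"unknown format {fmt!r}")
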