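"""Mapper network construction.

Covers the 2-D lens with an overlapping rectangular grid, density-clusters
each bin's members with DBSCAN on the original-space (Bray-Curtis)
distances, and takes the nerve: one node per cluster, an edge whenever two
nodes share a sample. Tracks the cover ratio (fraction of samples retained
in at least one node) and the dropped samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from microstrat.geometry import DistanceMatrix, Lens, expected_clusters, h0_persistence
from microstrat.io_metadata import ValidationError

DEFAULT_RESOLUTION = 85
DEFAULT_OVERLAP = 0.85
DEFAULT_MIN_SAMPLES = 5
DEFAULT_EPS_THRESHOLD = 0.95


@dataclass
class CoverBin:
    """One rectangle of the overlapping grid cover with its member samples."""

    index: tuple[int, int]
    x_interval: tuple[float, float]
    y_interval: tuple[float, float]
    member_samples: list[str]


@dataclass
class Node:
    members: frozenset[str]
    bin_index: tuple[int, int]
    centroid: tuple[float, float]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TDANetwork:
    """Mapper output: cluster nodes, shared-sample edges, parameters."""

    nodes: dict[int, Node]
    edges: set[tuple[int, int]]
    params: dict = field(default_factory=dict)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    @property
    def retained_samples(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out |= node.members
        return out

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def n_components(self) -> int:
        if not self.nodes:
            return 0
        return nx.number_connected_components(self.graph())


def axis_intervals(
    vmin: float, vmax: float, resolution: int, overlap: float
) -> list[tuple[float, float]]:
    """Overlapping 1-D cover: base width w = range/resolution, each base
    interval widened symmetrically by overlap * w / 2 on both sides.

    A degenerate axis (zero range) yields a single interval.
    """
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")
    if not (0 <= overlap < 1):
        raise ValidationError("overlap must lie in [0, 1)")
    span = vmax - vmin
    if span <= 0:
        return [(vmin, vmax)]
    w = span / resolution
    pad = overlap * w / 2.0
    return [
        (vmin + i * w - pad, vmin + (i + 1) * w + pad) for i in range(resolution)
    ]


def build_cover(lens: Lens, resolution: int, overlap: float) -> list[CoverBin]:
    """Grid product of the per-axis overlapping intervals; only non-empty
    bins are returned. Every sample lies in at least one bin."""
    x = lens.coords[:, 0]
    y = lens.coords[:, 1]
    xs = axis_intervals(float(x.min()), float(x.max()), resolution, overlap)
    ys = axis_intervals(float(y.min()), float(y.max()), resolution, overlap)
    samples = np.asarray(lens.sample_ids, dtype=object)
    bins: list[CoverBin] = []
    for i, (xlo, xhi) in enumerate(xs):
        in_x = (x >= xlo) & (x <= xhi)
        if not in_x.any():
            continue
        for j, (ylo, yhi) in enumerate(ys):
            mask = in_x & (y >= ylo) & (y <= yhi)
            if mask.any():
                bins.append(
                    CoverBin(
                        index=(i, j),
                        x_interval=(xlo, xhi),
                        y_interval=(ylo, yhi),
                        member_samples=list(samples[mask]),
                    )
                )
    return bins


def optimize_eps(D: DistanceMatrix, coverage_threshold: float = 0.95) -> float:
    """DBSCAN eps from the nearest-neighbour distance distribution.

    Returns the nearest-rank ``coverage_threshold`` quantile of each
    sample's distance to its closest other sample, so that roughly that
    fraction of samples can reach a neighbour within eps.
    """
    if D.n < 2:
        raise ValidationError("need at least 2 samples to optimize eps")
    if not (0 < coverage_threshold <= 1):
        raise ValidationError("coverage_threshold must lie in (0, 1]")
    off = D.values + np.diag(np.full(D.n, np.inf))
    nn = off.min(axis=1)
    nn_sorted = np.sort(nn)
    rank = int(np.ceil(coverage_threshold * D.n)) - 1
    return float(nn_sorted[max(rank, 0)])


def cluster_bin(
    cover_bin: CoverBin,
    D: DistanceMatrix,
    eps: float,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[set[str]]:
    """DBSCAN on the original-space distance submatrix of one bin.

    Core points have >= min_samples neighbours within eps (self included);
    clusters are eps-connected components of core points plus their border
    points. Noise samples are dropped (returned in no cluster).
    """
    members = cover_bin.member_samples
    if not members:
        return []
    if len(members) < min_samples:
        return []
    index = {s: i for i, s in enumerate(D.sample_ids)}
    rows = [index[s] for s in members]
    sub = D.values[np.ix_(rows, rows)]
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(sub).labels_
    clusters: dict[int, set[str]] = {}
    for sample, lab in zip(members, labels):
        if lab >= 0:
            clusters.setdefault(int(lab), set()).add(sample)
    return [clusters[k] for k in sorted(clusters)]


def build_network(
    cover: list[CoverBin],
    clusters_per_bin: list[list[set[str]]],
    lens: Lens,
    params: dict | None = None,
) -> TDANetwork:
    """Nerve of the clustered cover: one node per cluster, an edge exactly
    when two nodes share at least one sample."""
    if len(cover) != len(clusters_per_bin):
        raise ValidationError("clusters_per_bin must align with cover")
    pos = {s: lens.coords[i] for i, s in enumerate(lens.sample_ids)}
    nodes: dict[int, Node] = {}
    nid = 0
    for cover_bin, clusters in zip(cover, clusters_per_bin):
        bin_members = set(cover_bin.member_samples)
        for cluster in clusters:
            if not cluster:
                raise ValidationError("empty cluster passed to build_network")
            if not cluster <= bin_members:
                raise ValidationError(
                    f"cluster in bin {cover_bin.index} contains non-member samples"
                )
            coords = np.array([pos[s] for s in sorted(cluster)])
            nodes[nid] = Node(
                members=frozenset(cluster),
                bin_index=cover_bin.index,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
            )
            nid += 1
    # shared-sample relation via sample -> node incidence
    incidence: dict[str, list[int]] = {}
    for node_id, node in nodes.items():
        for s in node.members:
            incidence.setdefault(s, []).append(node_id)
    edges: set[tuple[int, int]] = set()
    for node_ids in incidence.values():
        node_ids.sort()
        for a in range(len(node_ids)):
            for b in range(a + 1, len(node_ids)):
                edges.add((node_ids[a], node_ids[b]))
    return TDANetwork(nodes=nodes, edges=edges, params=dict(params or {}))


def cover_ratio(network: TDANetwork, n_total: int) -> float:
    """Fraction of input samples retained in at least one node."""
    if n_total < 1:
        raise ValidationError("n_total must be positive")
    retained = len(network.retained_samples)
    if retained > n_total:
        raise ValidationError("node union exceeds the stated sample total")
    return retained / n_total


def mapper_network(
    D: DistanceMatrix,
    lens: Lens,
    resolution: int = DEFAULT_RESOLUTION,
    overlap: float = DEFAULT_OVERLAP,
    eps: float | None = None,
    eps_threshold: float = DEFAULT_EPS_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> TDANetwork:
    """End-to-end Mapper: cover the lens, cluster every bin on the
    original-space distances, take the nerve."""
    if eps is None:
        eps = optimize_eps(D, eps_threshold)
    cover = build_cover(lens, resolution, overlap)
    clusters = [cluster_bin(b, D, eps=eps, min_samples=min_samples) for b in cover]
    params = {
        "resolution": resolution,
        "overlap": overlap,
        "eps": eps,
        "eps_threshold": eps_threshold,
        "min_samples": min_samples,
    }
    return build_network(cover, clusters, lens, params)


def parameter_sweep(
    D: DistanceMatrix,
    lens: Lens,
    resolutions: list[int],
    overlaps: list[float],
    eps_threshold: float = DEFAULT_EPS_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """Grid sweep over (resolution, overlap): cover ratio, node count,
    edge count, connected components, and the H0 high-persistence count
    for side-by-side comparison."""
    if not resolutions or not overlaps:
        raise ValidationError("sweep grids must be non-empty")
    eps = optimize_eps(D, eps_threshold)
    h0_clusters = expected_clusters(h0_persistence(D))
    rows = []
    for res in resolutions:
        for ov in overlaps:
            net = mapper_network(
                D, lens, resolution=res, overlap=ov, eps=eps, min_samples=min_samples
            )
            rows.append(
                {
                    "resolution": res,
                    "overlap": ov,
                    "cover_ratio": cover_ratio(net, D.n),
                    "n_nodes": len(net.nodes),
                    "n_edges": len(net.edges),
                    "n_components": net.n_components(),
                    "h0_clusters": h0_clusters,
                }
            )
    return pd.DataFrame(rows)


def write_network(network: TDANetwork, graphml_path, members_path) -> None:
    """GraphML export (size, centroid, member count per node) plus a
    sidecar JSON mapping node id -> member sample ids."""
    g = nx.Graph()
    for nid in network.node_ids:
        node = network.nodes[nid]
        g.add_node(
            nid,
            size=node.size,
            centroid_x=node.centroid[0],
            centroid_y=node.centroid[1],
            bin_i=node.bin_index[0],
            bin_j=node.bin_index[1],
        )
    g.add_edges_from(sorted(network.edges))
    nx.write_graphml(g, graphml_path)
    members = {str(nid): sorted(network.nodes[nid].members) for nid in network.node_ids}
    with open(members_path, "w") as fh:
        json.dump({"params": network.params, "members": members}, fh, indent=1, sort_keys=True)


def read_network(graphml_path, members_path) -> TDANetwork:
    g = nx.read_graphml(graphml_path, node_type=int)
    with open(members_path) as fh:
        sidecar = json.load(fh)
    nodes = {}
    for nid, data in g.nodes(data=True):
        nodes[int(nid)] = Node(
            members=frozenset(sidecar["members"][str(nid)]),
            bin_index=(int(data.get("bin_i", -1)), int(data.get("bin_j", -1))),
            centroid=(float(data.get("centroid_x", 0.0)), float(data.get("centroid_y", 0.0))),
        )
    edges = {tuple(sorted((int(a), int(b)))) for a, b in g.edges()}
    return TDANetwork(nodes=nodes, edges=edges, params=dict(sidecar.get("params", {})))
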