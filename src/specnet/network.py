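"""Assembly of accepted spectral pairs into subnetworks.

Edges are inserted in order of increasing pair p-value into a union-find
structure that tracks, per component, the set of distinct precursor-mass
bins among its members. An edge that would merge two components is skipped
when the merged inventory would exceed the configured maximum; this single
constraint splits mixed subnetworks caused by false pairs and multiplexed
(co-fragmented) spectra, whose alignments tend to have the weakest p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentResult
from .config import Config, log


@dataclass
class NetworkNode:
    spectrum_id: str
    precursor_mass: float
    species_label: str = ""


class _UnionFind:
    """Union-find over node ids with per-root precursor-mass-bin inventories."""

    def __init__(self, nodes: dict[str, NetworkNode], bin_width: float) -> None:
        self.parent = {i: i for i in nodes}
        self.rank = {i: 0 for i in nodes}
        self.inventory = {
            i: {int(round(n.precursor_mass / bin_width))} for i, n in nodes.items()
        }

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.inventory[ra] |= self.inventory.pop(rb)
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass
class SpectralNetwork:
    """Graph of spectra (nodes) and accepted pairs (edges) in components."""

    nodes: dict[str, NetworkNode]
    edges: list[AlignmentResult] = field(default_factory=list)
    skipped_edges: list[AlignmentResult] = field(default_factory=list)
    max_masses: int | None = None
    _uf: _UnionFind | None = None

    def component_of(self, spectrum_id: str) -> str:
        assert self._uf is not None
        return self._uf.find(spectrum_id)

    def components(self) -> list[set[str]]:
        assert self._uf is not None
        groups: dict[str, set[str]] = {}
        for i in self.nodes:
            groups.setdefault(self._uf.find(i), set()).add(i)
        return sorted(groups.values(), key=lambda s: min(s))

    def component_mass_bins(self, config: Config | None = None) -> dict[str, set[int]]:
        """Precursor-mass-bin inventory per component root."""
        assert self._uf is not None
        return {root: set(bins) for root, bins in self._uf.inventory.items()
                if self._uf.find(root) == root}

    def adjacency(self) -> dict[str, list[AlignmentResult]]:
        adj: dict[str, list[AlignmentResult]] = {i: [] for i in self.nodes}
        for e in self.edges:
            adj[e.id_1].append(e)
            adj[e.id_2].append(e)
        return adj

    def to_edge_table(self) -> pd.DataFrame:
        rows = [{
            "id_1": e.id_1, "id_2": e.id_2, "delta_mass": e.delta_mass,
            "t1": e.t1, "t2": e.t2, "p1": e.p1, "p2": e.p2,
            "pair_p": e.pair_p, "breakpoint": e.breakpoint,
        } for e in self.edges]
        return pd.DataFrame(rows, columns=["id_1", "id_2", "delta_mass", "t1",
                                           "t2", "p1", "p2", "pair_p",
                                           "breakpoint"])

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.Graph()
        for i, n in self.nodes.items():
            g.add_node(i, precursor_mass=n.precursor_mass,
                       species=n.species_label)
        for e in self.edges:
            g.add_edge(e.id_1, e.id_2, delta_mass=e.delta_mass,
                       pair_p=float(e.pair_p) if e.pair_p is not None else 1.0)
        nx.write_graphml(g, path)


def _sorted_edges(pairs: list[AlignmentResult]) -> list[AlignmentResult]:
    return sorted(pairs, key=lambda e: (
        e.pair_p if e.pair_p is not None else 1.0, e.id_1, e.id_2))


def build_network(pairs: list[AlignmentResult], nodes: dict[str, NetworkNode],
                  max_masses: int | None = None,
                  config: Config | None = None) -> SpectralNetwork:
    """Greedy constrained assembly of accepted pairs into subnetworks.

    Edges are considered once, by increasing pair p-value (ties by ids). An
    edge joining two components is skipped iff the union of their
    precursor-mass inventories would exceed ``max_masses`` distinct bins;
    edges inside a component are always kept. ``max_masses=None`` disables
    the constraint, giving plain connected components.
    """
    cfg = config or Config()
    if max_masses is not None and max_masses < 1:
        raise ValueError("max_masses must be >= 1")
    for e in pairs:
        if e.id_1 not in nodes or e.id_2 not in nodes:
            raise KeyError(f"edge ({e.id_1}, {e.id_2}) references unknown node")
    net = SpectralNetwork(nodes=dict(nodes), max_masses=max_masses)
    uf = _UnionFind(net.nodes, cfg.precursor_tolerance_da)
    net._uf = uf
    for e in _sorted_edges(pairs):
        ra, rb = uf.find(e.id_1), uf.find(e.id_2)
        if ra == rb:
            net.edges.append(e)
            continue
        if (max_masses is not None
                and len(uf.inventory[ra] | uf.inventory[rb]) > max_masses):
            net.skipped_edges.append(e)
            continue
        uf.union(e.id_1, e.id_2)
        net.edges.append(e)
    return net


def edge_fdr_cutoff(labeled: list[tuple[float, str]], target: float) -> float:
    """Largest p cutoff keeping the labeled-edge FDR at or below target.

    ``labeled`` is (pair_p, label) with labels in {"true", "ambiguous",
    "false"}; ambiguous edges do not enter the ratio. Returns the pair_p of
    the last edge in the longest p-sorted prefix whose cumulative
    false/(false+true) ratio is <= target, or -inf if even the first
    counted edge violates it.
    """
    if not labeled:
        raise ValueError("no labeled edges; supply seed annotations first")
    cutoff = -np.inf
    n_true = n_false = 0
    for p, lab in sorted(labeled, key=lambda x: x[0]):
        if lab == "true":
            n_true += 1
        elif lab == "false":
            n_false += 1
        elif lab != "ambiguous":
            raise ValueError(f"unknown label {lab!r}")
        if n_true + n_false == 0:
            cutoff = p
        elif n_false / (n_false + n_true) <= target:
            cutoff = p
    return cutoff


def filter_edges_by_fdr(network: SpectralNetwork,
                        labels: dict[tuple[str, str], str],
                        target_edge_fdr: float,
                        config: Config | None = None
                        ) -> tuple[SpectralNetwork, float]:
    """Remove edges above the p cutoff that brings the edge FDR to target.

    The cutoff is estimated on the labeled (seed-annotated) edges; all edges
    with pair_p above it are dropped and components are rebuilt under the
    same precursor-mass constraint. Returns the filtered network and cutoff.
    """
    labeled = [(e.pair_p, labels[e.key]) for e in network.edges
               if e.key in labels and e.pair_p is not None]
    cutoff = edge_fdr_cutoff(labeled, target_edge_fdr)
    kept = [e for e in network.edges
            if e.pair_p is not None and e.pair_p <= cutoff]
    log.info("edge-FDR filter: cutoff %.3g keeps %d/%d edges",
             cutoff, len(kept), len(network.edges))
    return build_network(kept, network.nodes, network.max_masses, config), cutoff


def component_summary(network: SpectralNetwork,
                      config: Config | None = None) -> pd.DataFrame:
    """Per-component size, species count, distinct masses, variant flag."""
    comp_ids = {i: network.component_of(i) for i in network.nodes}
    rows = {}
    for cid in set(comp_ids.values()):
        members = [i for i, c in comp_ids.items() if c == cid]
        species = {network.nodes[i].species_label for i in members}
        bins = network.component_mass_bins(config).get(cid, set())
        rows[cid] = {"component": cid, "size": len(members),
                     "n_species": len(species), "n_masses": len(bins),
                     "has_variant_pair": False}
    for e in network.edges:
        if abs(e.delta_mass) > 5.0:
            rows[comp_ids[e.id_1]]["has_variant_pair"] = True
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["component"]))
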