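"""Merge spectral, mass-difference and homologous-series networks into
one typed graph.

Node identity is the feature id: all three builders operate on the same
feature table, so no tolerance-based node merging is needed.  Each
unordered node pair carries exactly one edge whose ``types`` attribute
records which source networks contained it; per-type evidence (cosine,
matched transformations, series memberships) is retained on the edge.
Features without any edge are kept as singleton nodes so that reports
cover the whole table, and features without MS2 spectra can still carry
mass-difference or homolog edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .formula import Transformation
from .homologs import SeriesCluster, homolog_edges
from .io import Feature
from .massdiff import MassDiffEdge
from .spectral import SpectralEdge

__all__ = ["TypedEdge", "MergedNetwork", "merge_networks", "write_graphml", "read_graphml"]

EDGE_TYPES = ("spectral", "massdiff", "homolog")


@dataclass
class TypedEdge:
    """The single merged edge between one node pair."""

    id_a: str
    id_b: str
    types: set[str] = field(default_factory=set)
    cosine: float | None = None
    matched_peaks: int | None = None
    transformations: list[MassDiffEdge] = field(default_factory=list)
    series_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


class MergedNetwork:
    """Typed feature graph: nodes are features, edges are TypedEdges."""

    def __init__(self, features: Iterable[Feature]):
        self.features: dict[str, Feature] = {}
        for f in features:
            if f.id in self.features:
                raise ValueError(f"duplicate feature id {f.id!r}")
            self.features[f.id] = f
        self.edges: dict[tuple[str, str], TypedEdge] = {}

    # -- construction -------------------------------------------------
    def _edge(self, a: str, b: str) -> TypedEdge:
        for fid in (a, b):
            if fid not in self.features:
                raise KeyError(f"edge endpoint {fid!r} is not a known feature")
        key = (a, b) if a < b else (b, a)
        if key not in self.edges:
            self.edges[key] = TypedEdge(*key)
        return self.edges[key]

    def add_spectral(self, e: SpectralEdge) -> None:
        te = self._edge(e.id_a, e.id_b)
        te.types.add("spectral")
        te.cosine = e.cosine
        te.matched_peaks = e.matched_peaks

    def add_massdiff(self, e: MassDiffEdge) -> None:
        te = self._edge(e.id_a, e.id_b)
        te.types.add("massdiff")
        te.transformations.append(e)

    def add_homolog(self, id_a: str, id_b: str, series_id: int) -> None:
        te = self._edge(id_a, id_b)
        te.types.add("homolog")
        if series_id not in te.series_ids:
            te.series_ids.append(series_id)

    # -- queries ------------------------------------------------------
    def neighbors(self, fid: str) -> list[str]:
        out = [b if a == fid else a for (a, b) in self.edges if fid in (a, b)]
        return sorted(out)

    def edge(self, a: str, b: str) -> TypedEdge | None:
        return self.edges.get((a, b) if a < b else (b, a))

    @property
    def n_nodes(self) -> int:
        return len(self.features)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self, annotations: Iterable | None = None) -> nx.Graph:
        """Export to a networkx graph with viewer-friendly attributes.

        Edge types are stored both comma-joined (``types``) and as one
        boolean per type, for styling in e.g. Cytoscape.
        """
        g = nx.Graph()
        for f in self.features.values():
            g.add_node(f.id, mz=f.mz, rt=f.rt, intensity=f.intensity,
                       polarity=f.polarity)
        for te in self.edges.values():
            attrs: dict = {"types": ",".join(sorted(te.types))}
            for t in EDGE_TYPES:
                attrs[t] = t in te.types
            if te.cosine is not None:
                attrs["cosine"] = float(te.cosine)
                attrs["matched_peaks"] = int(te.matched_peaks or 0)
            if te.transformations:
                attrs["transformations"] = ";".join(
                    f"{m.transformation.name}:{m.transformation.delta_mass:.6f}"
                    f":{m.deviation:.6f}"
                    for m in te.transformations
                )
            if te.series_ids:
                attrs["series_ids"] = ",".join(str(s) for s in te.series_ids)
            g.add_edge(te.id_a, te.id_b, **attrs)
        if annotations is not None:
            for a in annotations:
                node = g.nodes[a.feature_id]
                node.setdefault("annotation", a.name)
                node.setdefault("annotation_formula",
                                str(a.formula) if a.formula else "")
                node.setdefault("annotation_level", "+".join(sorted(a.level)))
        return g


def merge_networks(
    spectral_edges: Iterable[SpectralEdge],
    massdiff_edges: Iterable[MassDiffEdge],
    series: Iterable[SeriesCluster] | Sequence[tuple[str, str, int]],
    features: Iterable[Feature],
) -> MergedNetwork:
    """Build the merged typed graph from the three edge sets.

    ``series`` may be the series clusters themselves (consecutive-member
    edges are derived) or a pre-built homolog edge list.  Merging is
    order-independent: every pair ends up with one edge whose type set
    and attributes do not depend on input ordering.
    """
    net = MergedNetwork(features)
    for e in spectral_edges:
        net.add_spectral(e)
    for e in massdiff_edges:
        net.add_massdiff(e)
    series = list(series)
    if series and isinstance(series[0], SeriesCluster):
        series = homolog_edges(series)
    for a, b, sid in series:
        net.add_homolog(a, b, sid)
    # deterministic attribute order regardless of input order
    for te in net.edges.values():
        te.transformations.sort(key=lambda m: (m.transformation.delta_mass,
                                               m.transformation.name))
        te.series_ids.sort()
    return net


def write_graphml(net: MergedNetwork, path: str | Path,
                  annotations: Iterable | None = None) -> None:
    nx.write_graphml(net.to_networkx(annotations), str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
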