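"""Two-mode graphs of the metabolic hierarchy, age slices and projections.

The system is represented as an undirected bipartite graph between
category nodes (subnetworks, or mesonetworks after membership union)
and enzyme nodes.  Cutting the enzyme set at an age threshold t yields
a growing family of slices along the timeline; each slice is decomposed
into its two one-mode projections, where two same-side nodes are linked
with weight equal to the number of counterpart nodes they share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import networkx as nx

from metanet.io import Dataset

Level = Literal["mesonetwork", "subnetwork"]
Side = Literal["category", "enzyme"]


@dataclass
class BipartiteSlice:
    """Two-mode category–enzyme graph restricted to enzymes of age <= t."""

    level: Level
    t: float
    graph: nx.Graph  # node attr 'kind' in {'category', 'enzyme'}; enzymes carry 'age'

    @property
    def category_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "category"}

    @property
    def enzyme_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "enzyme"}


@dataclass
class ProjectionGraph:
    """Weighted one-mode projection of a bipartite slice."""

    side: Side
    t: float
    graph: nx.Graph  # edge attr 'weight' = shared counterpart count


def build_bipartite(ds: Dataset, ages: Mapping[str, float], level: Level) -> BipartiteSlice:
    """Full (t = 1.0) bipartite graph at the requested hierarchy level.

    At mesonetwork level an enzyme links to the union of its
    subnetworks' mesonetworks.  Enzymes without an age or without any
    membership are absent; categories left without enzymes are dropped.
    """
    if level not in ("mesonetwork", "subnetwork"):
        raise ValueError(f"unknown level: {level!r}")
    meso_of = ds.meso_of()
    g = nx.Graph()
    for ec, map_id in zip(ds.membership["ec"], ds.membership["map_id"]):
        if ec not in ages or map_id not in meso_of:
            continue
        cat = meso_of[map_id] if level == "mesonetwork" else map_id
        if cat not in g:
            g.add_node(cat, kind="category")
        if ec not in g:
            g.add_node(ec, kind="enzyme", age=float(ages[ec]))
        g.add_edge(cat, ec)
    return BipartiteSlice(level=level, t=1.0, graph=g)


def slice_by_age(b: BipartiteSlice, t: float) -> BipartiteSlice:
    """Retain enzymes of age <= t; drop categories left with no enzyme."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold outside [0, 1]: {t}")
    g = b.graph
    keep_enzymes = {n for n, d in g.nodes(data=True) if d["kind"] == "enzyme" and d["age"] <= t}
    keep_cats = {c for c, d in g.nodes(data=True) if d["kind"] == "category"
                 and any(e in keep_enzymes for e in g.neighbors(c))}
    sub = g.subgraph(keep_enzymes | keep_cats).copy()
    return BipartiteSlice(level=b.level, t=t, graph=sub)


def project_one_mode(b: BipartiteSlice, side: Side) -> ProjectionGraph:
    """One-mode projection; weight(u, v) = |N(u) ∩ N(v)| in the slice.

    All nodes of the chosen side are kept, including those that end up
    isolated (they count in totals; component-level statistics are
    computed on the largest connected component anyway).
    """
    if side not in ("category", "enzyme"):
        raise ValueError(f"unknown side: {side!r}")
    g = b.graph
    own = [n for n, d in g.nodes(data=True) if d["kind"] == side]
    proj = nx.Graph()
    proj.add_nodes_from(own)
    for counterpart, d in g.nodes(data=True):
        if d["kind"] == side:
            continue
        neigh = sorted(g.neighbors(counterpart))
        for i, u in enumerate(neigh):
            for v in neigh[i + 1:]:
                if proj.has_edge(u, v):
                    proj[u][v]["weight"] += 1
                else:
                    proj.add_edge(u, v, weight=1)
    return ProjectionGraph(side=side, t=b.t, graph=proj)


def largest_component(g: nx.Graph) -> nx.Graph:
    """Node-maximal connected subgraph; ties to the smallest member label."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no largest component")
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    best_size = max(len(c) for c in comps)
    # among equal sizes, the component whose smallest member sorts first
    best = min((c for c in comps if len(c) == best_size), key=lambda c: str(c[0]))
    return g.subgraph(best).copy()


def reduce_representation(g_or_proj: ProjectionGraph | nx.Graph, min_weight: int = 1):
    """Threshold a weighted projection and attach greyscale edge shades.

    Edges below ``min_weight`` and nodes left isolated are dropped;
    each surviving edge gets ``greyscale`` = weight / max-weight, so the
    heaviest sharing renders black (1.0) and the lightest near white.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    proj = g_or_proj if isinstance(g_or_proj, nx.Graph) else g_or_proj.graph
    keep = [(u, v, d) for u, v, d in proj.edges(data=True) if d["weight"] >= min_weight]
    out = nx.Graph()
    if not keep:
        warnings.warn("weight threshold removed every edge", stacklevel=2)
        if isinstance(g_or_proj, ProjectionGraph):
            return ProjectionGraph(side=g_or_proj.side, t=g_or_proj.t, graph=out)
        return out
    wmax = max(d["weight"] for _, _, d in keep)
    for u, v, d in keep:
        out.add_edge(u, v, weight=d["weight"], greyscale=d["weight"] / wmax)
    if isinstance(g_or_proj, ProjectionGraph):
        return ProjectionGraph(side=g_or_proj.side, t=g_or_proj.t, graph=out)
    return out
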