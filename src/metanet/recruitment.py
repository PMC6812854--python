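"""Recruitment patterns, clustering and annotation distributions.

Recruitment is read off the membership structure: which subnetworks
gained enzymes in which era (sharing matrix), how many enzymes each
mesonetwork pair shares at each threshold (link tables), and how the
subnetwork projection organises into clusters (classic Ward on squared
Euclidean dissimilarities of adjacency rows) with its modularity-matrix
"tapestry" heatmap.  Taxonomic (Venn superkingdom groups), functional
(7 general / 50 detailed categories) and catalytic-residue
distributions complete the picture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from metanet.chronology import bin_to_era
from metanet.io import Dataset
from metanet.netbuild import BipartiteSlice, ProjectionGraph, project_one_mode

logger = logging.getLogger(__name__)

SUPERKINGDOM_ORDER = "ABEV"

#: default chemical grouping of the 20 canonical residues; glycine is
#: placed with the polar-uncharged set (the assignment is configurable
#: because conventions differ)
DEFAULT_RESIDUE_GROUPS: dict[str, str] = {
    **{r: "basic" for r in "KRH"},
    **{r: "acidic" for r in "DE"},
    **{r: "polar_uncharged" for r in "STNQCYG"},
    **{r: "nonpolar" for r in "AVLIPFMW"},
}


# --------------------------------------------------------------------------
# sharing / link tables

def sharing_matrix(ds: Dataset, ages: Mapping[str, float], era_width: float = 0.1) -> pd.DataFrame:
    """Subnetwork × era matrix of enzyme counts.

    cell(s, era) = number of enzymes belonging to subnetwork s whose
    assigned age falls in that era; an enzyme in several subnetworks
    contributes once per subnetwork, so row sums equal per-subnetwork
    enzyme counts.  Rows are grouped by mesonetwork, then map id.
    """
    n_eras = round(1.0 / era_width)
    meso_of = ds.meso_of()
    rows = sorted(
        ((meso_of[m], m) for m in ds.hierarchy["map_id"]),
        key=lambda p: (p[0], p[1]),
    )
    idx = pd.MultiIndex.from_tuples(rows, names=["meso_code", "map_id"])
    mat = pd.DataFrame(0, index=idx, columns=pd.Index(range(1, n_eras + 1), name="era"))
    seen = set()
    for ec, m in zip(ds.membership["ec"], ds.membership["map_id"]):
        if ec not in ages or m not in meso_of or (ec, m) in seen:
            continue
        seen.add((ec, m))
        mat.loc[(meso_of[m], m), bin_to_era(ages[ec], era_width)] += 1
    return mat


def meso_link_table(slices: Sequence[BipartiteSlice]) -> pd.DataFrame:
    """Long table of mesonetwork pairs with shared-enzyme counts per t.

    weight(M1, M2; t) counts enzymes of age <= t belonging to both
    mesonetworks — identical to the category projection's edge weights
    at each threshold.
    """
    out = []
    for sl in slices:
        proj = project_one_mode(sl, "category")
        for u, v, d in proj.graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            out.append((sl.t, a, b, int(d["weight"])))
    return pd.DataFrame(out, columns=["t", "source", "target", "weight"]).sort_values(
        ["t", "source", "target"]
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# classic Ward clustering (Lance–Williams on squared Euclidean input)

@dataclass
class Dendrogram:
    """Agglomeration record: scipy-style merge list plus leaf labels.

    ``merges[i] = (a, b, height, size)`` joins clusters a and b into
    cluster ``n_leaves + i``; ids < n_leaves are leaves.  Heights are
    non-decreasing (Ward is monotone).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the merge tree."""
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _, _ = self.merges[node - n]
            return walk(a) + walk(b)

        root = n + len(self.merges) - 1 if self.merges else 0
        return [self.labels[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        heights = [0.0] * n + [m[2] for m in self.merges]

        def render(node: int, parent_h: float) -> str:
            bl = max(0.0, parent_h - heights[node])
            if node < n:
                return f"{self.labels[node]}:{bl:g}"
            a, b, h, _ = self.merges[node - n]
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        if not self.merges:
            return f"{self.labels[0]}:0;" if self.labels else ";"
        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"


def _as_matrix(m) -> tuple[np.ndarray, list]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), list(m.index)
    arr = np.asarray(m, dtype=float)
    return arr, list(range(arr.shape[0]))


def ward_cluster(matrix) -> Dendrogram:
    """Classic Ward agglomeration of the rows of a weighted adjacency.

    Dissimilarity is the squared Euclidean distance between rows;
    merging follows the Lance–Williams update for Ward's minimum
    variance criterion applied to squared distances (the convention in
    which distances are *not* squared again internally).  Ties are
    broken by the lexicographically smallest pair of cluster
    representative labels, making the tree deterministic.
    """
    arr, labels = _as_matrix(matrix)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("ward_cluster expects a square (adjacency) matrix")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")

    # squared Euclidean distances between rows
    sq = np.sum(arr**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (arr @ arr.T)
    d[d < 0] = 0.0  # numerical noise
    np.fill_diagonal(d, np.inf)

    size = {i: 1 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}       # lexicographic tie-break key
    active = set(range(n))
    dist = {frozenset((i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    while len(active) > 1:
        best = min(
            (pair for pair in dist if pair <= active),
            key=lambda p: (dist[p], tuple(sorted(rep[x] for x in p))),
        )
        i, j = sorted(best, key=lambda x: rep[x])
        h = dist[best]
        new = next_id
        next_id += 1
        merges.append((i, j, h, size[i] + size[j]))
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
        active -= {i, j}
        for w in active:
            dij = dist[frozenset((i, j))]
            diw = dist[frozenset((i, w))]
            djw = dist[frozenset((j, w))]
            si, sj, sw = size[i], size[j], size[w]
            dnew = ((si + sw) * diw + (sj + sw) * djw - sw * dij) / (si + sj + sw)
            dist[frozenset((new, w))] = dnew
        active.add(new)

    return Dendrogram(labels=labels, merges=merges)


# --------------------------------------------------------------------------
# modularity heatmap matrix

def modularity_heatmap_matrix(g, weighted: bool = True, order: Sequence[str] | None = None) -> pd.DataFrame:
    """Scaled modularity matrix B = A − k kᵀ/(2m), rows in dendrogram order.

    With weights, A is the weighted adjacency and k the node strengths;
    the matrix is divided by max |B| so entries span [−1, 1].  Rows and
    columns follow the Ward dendrogram leaf order of the adjacency
    (or an explicit ``order``).
    """
    if isinstance(g, ProjectionGraph):
        g = g.graph
    if g.number_of_edges() == 0:
        raise ValueError("modularity matrix undefined on an edgeless graph")
    nodes = sorted(g.nodes(), key=str)
    weight = "weight" if weighted else None
    a = nx.to_numpy_array(g, nodelist=nodes, weight=weight)
    k = a.sum(axis=1)
    two_m = a.sum()
    b = a - np.outer(k, k) / two_m
    b = b / np.max(np.abs(b))
    df = pd.DataFrame(b, index=nodes, columns=nodes)
    if order is None:
        adj = pd.DataFrame(a, index=nodes, columns=nodes)
        order = ward_cluster(adj).leaf_order()
    return df.loc[list(order), list(order)]


# --------------------------------------------------------------------------
# Venn taxonomic groups

def venn_label(letters) -> str:
    bad = set(letters) - set(SUPERKINGDOM_ORDER)
    if bad:
        raise ValueError(f"unknown superkingdom letter(s): {sorted(bad)}")
    return "".join(l for l in SUPERKINGDOM_ORDER if l in set(letters))


def read_revisions(path) -> dict[str, set[str]]:
    """Read an EC revision table (columns old_ec, new_ec; one successor per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("old_ec", "new_ec"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.old_ec), set()).add(str(r.new_ec))
    return out


def venn_assign(
    taxa: Mapping[str, frozenset[str] | set[str]],
    revisions: Mapping[str, set[str]] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """ec -> Venn group label; returns (assignments, excluded ECs).

    Direct annotations map straight to the ordered letter label.  An EC
    revised into several successors is annotated only when every
    successor is annotated and all agree on the letter set (absolute
    consensus); disagreement or missing successors exclude the EC, with
    a logged reason.  Empty letter sets stay unannotated.
    """
    out: dict[str, str] = {}
    excluded: list[str] = []
    for ec, letters in taxa.items():
        if letters:
            out[ec] = venn_label(letters)
    for old, news in (revisions or {}).items():
        sets = [frozenset(taxa.get(n, frozenset())) for n in news]
        if sets and all(sets) and len(set(sets)) == 1:
            out[old] = venn_label(sets[0])
        else:
            excluded.append(old)
            logger.info("EC %s excluded: successors %s lack consensus", old, sorted(news))
    return out, sorted(excluded)


# --------------------------------------------------------------------------
# functional and catalytic distributions

def functional_distribution(
    ds: Dataset,
    ages: Mapping[str, float],
    functions: pd.DataFrame,
    venn: Mapping[str, str] | None = None,
    era_width: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(general × Venn group) and (detailed × era) enzyme counts.

    Domain fold families map to superfamily functional categories; an
    enzyme contributes one count per *distinct* category among its
    domains.  Domains whose superfamily lacks a category fall into an
    'Unannotated' bucket (logged).  The era comes from the enzyme's
    assigned age; the Venn column requires a taxa assignment and is
    empty otherwise.
    """
    fun = {str(r.fsf_id): (str(r.general), str(r.detailed)) for r in functions.itertuples()}
    venn = venn or {}
    n_eras = round(1.0 / era_width)

    gen_rows: dict[tuple[str, str], int] = {}
    det = pd.DataFrame()
    det_rows: dict[tuple[str, int], int] = {}
    n_unannotated = 0
    for ec, ccs_list in ds.domains.groupby("ec")["scop_ccs"]:
        generals, details = set(), set()
        for ccs in ccs_list:
            fsf = ".".join(str(ccs).split(".")[:3])
            if fsf in fun:
                g, d = fun[fsf]
                generals.add(g)
                details.add(d)
            else:
                generals.add("Unannotated")
                n_unannotated += 1
        vg = venn.get(str(ec), "unassigned")
        for g in generals:
            gen_rows[(g, vg)] = gen_rows.get((g, vg), 0) + 1
        if ec in ages:
            era = bin_to_era(ages[str(ec)], era_width)
            for d in details:
                det_rows[(d, era)] = det_rows.get((d, era), 0) + 1
    if n_unannotated:
        logger.info("%d domain assignments without functional category", n_unannotated)

    gen = pd.Series(gen_rows).unstack(fill_value=0) if gen_rows else pd.DataFrame()
    gen.index.name, gen.columns.name = "general", "venn_group"
    if det_rows:
        det = pd.Series(det_rows).unstack(fill_value=0)
        det = det.reindex(columns=range(1, n_eras + 1), fill_value=0)
    det.index.name, det.columns.name = "detailed", "era"
    return gen.sort_index(), det.sort_index()


def catalytic_distribution(
    catalysis: pd.DataFrame,
    venn: Mapping[str, str],
    ages: Mapping[str, float],
    residue_groups: Mapping[str, str] | None = None,
    era_width: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Catalytic residue counts by chemical group × (Venn group | era).

    Each catalytic-site residue of each enzyme counts once; residues
    map to basic / acidic / polar-uncharged / nonpolar through a
    configurable grouping table.  Unknown residue codes are an error.
    """
    groups = dict(residue_groups or DEFAULT_RESIDUE_GROUPS)
    n_eras = round(1.0 / era_width)
    by_venn: dict[tuple[str, str], int] = {}
    by_era: dict[tuple[str, int], int] = {}
    for r in catalysis.itertuples():
        res = str(r.residue)
        if res not in groups:
            raise ValueError(f"unknown residue code: {res!r}")
        grp = groups[res]
        vg = venn.get(str(r.ec))
        if vg:
            by_venn[(grp, vg)] = by_venn.get((grp, vg), 0) + 1
        if str(r.ec) in ages:
            era = bin_to_era(ages[str(r.ec)], era_width)
            by_era[(grp, era)] = by_era.get((grp, era), 0) + 1
    gv = pd.Series(by_venn).unstack(fill_value=0) if by_venn else pd.DataFrame()
    gv.index.name, gv.columns.name = "role_group", "venn_group"
    ge = pd.Series(by_era).unstack(fill_value=0) if by_era else pd.DataFrame()
    if by_era:
        ge = ge.reindex(columns=range(1, n_eras + 1), fill_value=0)
    ge.index.name, ge.columns.name = "role_group", "era"
    return gv.sort_index(), ge.sort_index()
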