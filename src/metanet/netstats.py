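"""Statistical battery for evolving graphs.

Every age slice of every graph (two-mode and both projections) is run
through the same set of measurements:

* average degree and diameter of the largest connected component;
* a discrete power-law fit of the degree sequence — maximum-likelihood
  exponent with the lower cutoff xmin selected by minimising the
  Kolmogorov–Smirnov distance, and a semi-parametric bootstrap
  goodness-of-fit p-value (null: the data come from the fitted law);
* the Bartels rank von Neumann test of randomness on the degree
  sequence, with the symmetric-Beta approximation of RVN/4 for
  p-values (expectation of RVN is 2 under exchangeability);
* small-world coefficients against an ensemble of Erdős–Rényi G(n, m)
  graphs matched to the LCC: S = (C_g/C_rand) / (L_g/L_rand);
* fast-greedy (agglomerative) maximum-modularity community structure;
* the hierarchical-modularity scaling C(k) ~ k^-1, measured as an OLS
  slope of log10 mean clustering per degree class against log10 k;
* degree / betweenness / closeness centralities with deterministic
  lexicographic tie-breaking.

Graphs are held as :mod:`networkx` objects; the distance-, triangle-
and community-based primitives run through :mod:`igraph`'s C core so
the battery stays fast at the full enzyme-projection scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from metanet.netbuild import BipartiteSlice, ProjectionGraph, largest_component

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawFit",
    "BartelsResult",
    "SmallWorldResult",
    "CkScalingFit",
    "ModularityResult",
    "CentralityTable",
    "MetricsConfig",
    "degree_diameter",
    "fit_power_law",
    "sample_discrete_power_law",
    "bartels_rank_test",
    "er_random_graph",
    "small_world",
    "fast_greedy_modularity",
    "ck_scaling",
    "centralities",
    "metrics_timeline",
]


# --------------------------------------------------------------------------
# results containers

@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    logLik: float
    ks_stat: float
    ks_p: float
    n_tail: int


@dataclass
class BartelsResult:
    rvn: float
    statistic: float
    p_value: float
    n: int


@dataclass
class SmallWorldResult:
    c_g: float
    l_g: float
    c_rand: float
    l_rand: float
    gamma: float
    lam: float
    s: float


@dataclass
class CkScalingFit:
    slope: float
    intercept: float
    r2: float
    n_classes: int


@dataclass
class ModularityResult:
    membership: dict
    q: float


@dataclass
class CentralityTable:
    table: pd.DataFrame           # index node; columns degree, betweenness, closeness
    top: dict[str, list]          # metric -> ranked top-k node list


# --------------------------------------------------------------------------
# igraph bridge

def _to_igraph(g: nx.Graph, weight: str | None = None) -> tuple[ig.Graph, list]:
    """Convert a networkx graph to igraph; returns (graph, node order)."""
    nodes = list(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    if weight is not None:
        h.es["weight"] = [d.get(weight, 1) for _, _, d in g.edges(data=True)]
    return h, nodes


def _local_clustering(g: nx.Graph) -> dict:
    """Unweighted local clustering per node (NaN-free; deg<2 -> 0)."""
    h, nodes = _to_igraph(g)
    vals = h.transitivity_local_undirected(mode="zero")
    return dict(zip(nodes, vals))


def _mean_clustering_deg2(g: nx.Graph) -> float:
    """Mean local clustering over nodes of degree >= 2 (0 if none)."""
    h, nodes = _to_igraph(g)
    deg = h.degree()
    vals = h.transitivity_local_undirected(mode="zero")
    keep = [c for c, d in zip(vals, deg) if d >= 2]
    return float(np.mean(keep)) if keep else 0.0


def _avg_path_length(g: nx.Graph) -> float:
    h, _ = _to_igraph(g)
    return float(h.average_path_length(directed=False, unconn=True))


# --------------------------------------------------------------------------
# degree / diameter

def degree_diameter(g: nx.Graph) -> tuple[float, int]:
    """(average degree of the full graph, diameter of its LCC); unweighted."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    avg_deg = 2.0 * g.number_of_edges() / g.number_of_nodes()
    lcc = largest_component(g)
    if lcc.number_of_nodes() <= 1:
        return avg_deg, 0
    h, _ = _to_igraph(lcc)
    return avg_deg, int(h.diameter(directed=False))


# --------------------------------------------------------------------------
# discrete power law

def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _mle_alpha(tail: np.ndarray, xmin: int) -> tuple[float, float]:
    """Maximise the zeta-normalised discrete likelihood for x >= xmin."""
    n = tail.size
    slog = float(np.log(tail).sum())

    def nll(a: float) -> float:
        return n * math.log(_zeta(a, xmin)) + a * slog

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x), -float(res.fun)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between fitted and empirical tail CDFs (at observed x)."""
    srt = np.sort(tail)
    xs = np.unique(srt)
    z = _zeta(alpha, xmin)
    # both CDFs are step functions jumping at the same atoms: compare
    # their right-continuous values at the observed points
    fit_cdf = 1.0 - special.zeta(alpha, xs + 1) / z
    emp_cdf = np.searchsorted(srt, xs, side="right") / tail.size
    return float(np.max(np.abs(emp_cdf - fit_cdf)))


def _fit_fixed_xmin(x: np.ndarray, xmin: int) -> tuple[float, float, float, int]:
    tail = x[x >= xmin]
    alpha, loglik = _mle_alpha(tail, xmin)
    return alpha, loglik, _ks_distance(tail, alpha, xmin), tail.size


def _fit_core(x: np.ndarray, xmin: int | None, min_tail: int = 10,
              max_candidates: int = 50) -> tuple[float, int, float, float, int]:
    """(alpha, xmin, loglik, ks, n_tail); xmin=None searches observed values."""
    if xmin is not None:
        a, ll, ks, nt = _fit_fixed_xmin(x, xmin)
        return a, xmin, ll, ks, nt
    srt = np.sort(x)
    cands = np.unique(srt)
    tail_sizes = srt.size - np.searchsorted(srt, cands, side="left")
    cands = cands[tail_sizes >= min_tail]
    if cands.size == 0:
        cands = np.array([int(srt[0])])
    if cands.size > max_candidates:
        idx = np.unique(np.linspace(0, cands.size - 1, max_candidates).astype(int))
        cands = cands[idx]
    best = None
    for c in cands:
        a, ll, ks, nt = _fit_fixed_xmin(x, int(c))
        if best is None or ks < best[3]:
            best = (a, int(c), ll, ks, nt)
    return best


def sample_discrete_power_law(alpha: float, xmin: int, size: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF sampling of the zeta-normalised discrete law."""
    z = _zeta(alpha, xmin)
    cap = 100_000
    support = np.arange(xmin, xmin + cap)
    cdf = np.cumsum(support.astype(float) ** -alpha) / z
    u = rng.random(size)
    out = xmin + np.searchsorted(cdf, u, side="left")
    # rare draws beyond the tabulated support: bisect on the zeta tail
    for i in np.flatnonzero(out >= xmin + cap):
        lo = hi = xmin + cap
        while 1.0 - _zeta(alpha, hi + 1) / z < u[i]:
            hi *= 2
        while lo < hi:
            mid = (lo + hi) // 2
            if 1.0 - _zeta(alpha, mid + 1) / z >= u[i]:
                hi = mid
            else:
                lo = mid + 1
        out[i] = lo
    return out


def fit_power_law(
    degrees: Iterable[int],
    pvalue_method: Literal["bootstrap", "none"] = "bootstrap",
    reps: int = 100,
    seed: int = 0,
    xmin: int | None = None,
) -> PowerLawFit:
    """Discrete power-law MLE with KS xmin selection and bootstrap GOF.

    ``xmin=None`` searches over observed unique degrees for the cutoff
    minimising the KS distance; a fixed ``xmin`` skips the search.  The
    bootstrap p-value is semi-parametric: synthetic samples mix the
    fitted tail law with resampling of the observed body, each refit
    from scratch; p = fraction of synthetic KS distances at least as
    large as the observed one.  Low p (< 0.05) rejects the hypothesis
    that the data follow the fitted law.
    """
    x = np.asarray(list(degrees), dtype=np.int64)
    if x.size == 0:
        raise ValueError("empty degree sequence")
    if np.any(x <= 0):
        raise ValueError("power-law fitting requires strictly positive values")
    if np.unique(x).size == 1:
        raise ValueError("degenerate (constant) degree sequence")
    if x.size < 50:
        logger.warning("power-law fit on only %d observations", x.size)

    alpha, xmin_hat, loglik, ks, n_tail = _fit_core(x, xmin)

    ks_p = math.nan
    if pvalue_method == "bootstrap":
        rng = np.random.default_rng(seed)
        body = x[x < xmin_hat]
        p_tail = n_tail / x.size
        hits = 0
        for _ in range(reps):
            n_t = int((rng.random(x.size) < p_tail).sum())
            parts = []
            if n_t:
                parts.append(sample_discrete_power_law(alpha, xmin_hat, n_t, rng))
            if x.size - n_t:
                src = body if body.size else sample_discrete_power_law(
                    alpha, xmin_hat, x.size - n_t, rng)
                parts.append(rng.choice(src, size=x.size - n_t) if body.size else src)
            synth = np.concatenate(parts)
            _, _, _, ks_s, _ = _fit_core(synth, xmin)
            if ks_s >= ks:
                hits += 1
        ks_p = hits / reps
    elif pvalue_method != "none":
        raise ValueError(f"unknown pvalue_method: {pvalue_method!r}")

    return PowerLawFit(alpha=alpha, xmin=xmin_hat, logLik=loglik,
                       ks_stat=ks, ks_p=ks_p, n_tail=n_tail)


# --------------------------------------------------------------------------
# Bartels rank von Neumann test

def bartels_rank_test(series: Sequence[float],
                      p_method: Literal["beta", "normal"] = "beta") -> BartelsResult:
    """Bartels' rank version of the von Neumann ratio test of randomness.

    RVN = Σ (R_i − R_{i+1})² / Σ (R_i − R̄)² over the midranks R_i;
    E[RVN] = 2 under exchangeability.  The standardized statistic uses
    σ² = 4(n−2)(5n²−2n−9) / (5n(n+1)(n−1)²); two-sided p-values come
    from the symmetric Beta approximation of RVN/4 (normal fallback).
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("Bartels test needs n >= 10")
    if np.all(y == y[0]):
        raise ValueError("constant series: rank variance is zero")
    r = stats.rankdata(y)  # midranks for ties
    num = float(np.sum(np.diff(r) ** 2))
    den = float(np.sum((r - (n + 1) / 2.0) ** 2))
    if den == 0.0:
        raise ValueError("zero rank variance")
    rvn = num / den
    sigma2 = 4.0 * (n - 2) * (5 * n * n - 2 * n - 9) / (5.0 * n * (n + 1) * (n - 1) ** 2)
    statistic = (rvn - 2.0) / math.sqrt(sigma2)

    if p_method == "beta":
        b = 0.5 * (4.0 / sigma2 - 1.0)
        if b > 0:
            cdf = stats.beta.cdf(rvn / 4.0, b, b)
            p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
        else:
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(statistic))))
    elif p_method == "normal":
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(statistic))))
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")
    return BartelsResult(rvn=rvn, statistic=statistic, p_value=p, n=n)


# --------------------------------------------------------------------------
# ER null model and small-world coefficient

def er_random_graph(n: int, m: int, seed: int | np.random.Generator = 0) -> nx.Graph:
    """Uniform simple G(n, m) graph with exactly n nodes and m edges."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"edge count {m} outside [0, {max_m}] for n={n}")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(0, 2**31 - 1))
    return nx.gnm_random_graph(n, m, seed=seed)


def small_world(g, n_rand: int = 20, seed: int = 0) -> SmallWorldResult:
    """Small-world coefficient S = (C_g/C_rand)/(L_g/L_rand) on the LCC.

    Clustering averages run over degree >= 2 nodes (local clustering is
    undefined below); path lengths over connected LCC pairs.  The null
    values are means over ``n_rand`` seeded ER G(n, m) graphs matched
    to the LCC (path lengths over each ER graph's reachable pairs).
    """
    if isinstance(g, BipartiteSlice):
        raise ValueError("clustering is not defined for a two-mode graph; "
                         "project to one mode first")
    if isinstance(g, ProjectionGraph):
        g = g.graph
    lcc = largest_component(g)
    if lcc.number_of_nodes() < 4:
        raise ValueError("LCC too small for small-world statistics (need >= 4 nodes)")
    c_g = _mean_clustering_deg2(lcc)
    l_g = _avg_path_length(lcc)

    rng = np.random.default_rng(seed)
    n, m = lcc.number_of_nodes(), lcc.number_of_edges()
    cs, ls = [], []
    for _ in range(n_rand):
        er = er_random_graph(n, m, rng)
        cs.append(_mean_clustering_deg2(er))
        ls.append(_avg_path_length(er))
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    if c_rand == 0.0:
        raise ValueError("ER ensemble clustering is zero; graph too sparse — "
                         "increase n_rand or use a denser graph")
    gamma = c_g / c_rand
    lam = l_g / l_rand
    return SmallWorldResult(c_g=c_g, l_g=l_g, c_rand=c_rand, l_rand=l_rand,
                            gamma=gamma, lam=lam, s=gamma / lam)


# --------------------------------------------------------------------------
# modularity

def fast_greedy_modularity(g: nx.Graph, weighted: bool = True) -> ModularityResult:
    """Agglomerative greedy maximum-modularity communities (fast greedy).

    Returns the partition at the maximum-Q cut of the merge tree and
    its modularity score; edge weights (shared-counterpart counts) are
    used unless ``weighted=False``.
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    use_w = weighted and any("weight" in d for _, _, d in g.edges(data=True))
    h, nodes = _to_igraph(g, weight="weight" if use_w else None)
    w = h.es["weight"] if use_w else None
    clustering = h.community_fastgreedy(weights=w).as_clustering()
    q = clustering.modularity
    membership = dict(zip(nodes, clustering.membership))
    return ModularityResult(membership=membership, q=float(q))


# --------------------------------------------------------------------------
# C(k) hierarchical-modularity scaling

def ck_scaling(g: nx.Graph) -> CkScalingFit:
    """OLS fit of log10 mean-C(k) against log10 k over degree classes k >= 2.

    A slope near −1 with high r² is the hierarchical-modularity
    signature C(k) ~ k^−1; a complete graph gives slope 0.
    """
    if isinstance(g, ProjectionGraph):
        g = g.graph
    clus = _local_clustering(g)
    by_k: dict[int, list[float]] = {}
    for v, d in g.degree():
        if d >= 2:
            by_k.setdefault(d, []).append(clus[v])
    ks = sorted(k for k, vals in by_k.items() if np.mean(vals) > 0)
    means = [float(np.mean(by_k[k])) for k in ks]
    if ks and max(means) - min(means) < 1e-12:
        # flat C(k) (e.g. a complete graph): no scaling, zero strength
        return CkScalingFit(slope=0.0, intercept=float(np.log10(means[0])),
                            r2=0.0, n_classes=len(ks))
    if len(ks) < 3:
        raise ValueError("need >= 3 degree classes with nonzero mean clustering")
    logk = np.log10(ks)
    logc = np.log10([np.mean(by_k[k]) for k in ks])
    res = stats.linregress(logk, logc)
    return CkScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                        r2=float(res.rvalue ** 2), n_classes=len(ks))


# --------------------------------------------------------------------------
# centralities

def centralities(g: nx.Graph, k: int = 10) -> CentralityTable:
    """Degree, betweenness and closeness on the LCC with top-k rankings.

    Betweenness is the raw (unnormalised) shortest-path pair count;
    closeness the inverse mean distance within the LCC.  Rank ties are
    broken lexicographically by node id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    lcc = largest_component(g)
    h, nodes = _to_igraph(lcc)
    deg = dict(zip(nodes, h.degree()))
    # igraph betweenness counts each unordered pair once (nx convention /2
    # for undirected graphs gives the same number)
    btw = dict(zip(nodes, h.betweenness(directed=False)))
    if len(nodes) > 1:
        clo = dict(zip(nodes, h.closeness(mode="all")))
    else:
        clo = {nodes[0]: 0.0}
    table = pd.DataFrame({"degree": deg, "betweenness": btw, "closeness": clo})
    table = table.sort_index(key=lambda ix: ix.map(str))
    top = {
        metric: [n for n, _ in sorted(table[metric].items(),
                                      key=lambda kv: (-kv[1], str(kv[0])))[:k]]
        for metric in ("degree", "betweenness", "closeness")
    }
    return CentralityTable(table=table, top=top)


# --------------------------------------------------------------------------
# the full per-slice battery

@dataclass
class MetricsConfig:
    """Settings shared by every cell of the metrics timeline."""

    seed: int = 0
    n_rand: int = 20
    bootstrap_reps: int = 100
    pvalue_method: Literal["bootstrap", "none"] = "bootstrap"
    weighted_modularity: bool = True
    top_k: int = 10
    compute_ck: bool = True


_TIMELINE_COLUMNS = [
    "graph_type", "nd", "n_nodes", "n_nodes_lcc", "n_edges", "avg_degree",
    "diameter", "q_max", "alpha", "xmin", "logLik", "ks_stat", "ks_p",
    "bartels_stat", "bartels_p", "er_bartels_stat", "er_bartels_p",
    "c_g", "l_g", "c_rand", "l_rand", "gamma", "lambda", "s",
    "ck_slope", "ck_r2",
]


def _degree_series_lex(g: nx.Graph) -> list[int]:
    """LCC degree sequence ordered by lexicographic node id (Bartels input)."""
    lcc = largest_component(g)
    return [d for _, d in sorted(lcc.degree(), key=lambda kv: str(kv[0]))]


def _try(key: str, fn, context: str):
    try:
        return fn()
    except (ValueError, ZeroDivisionError) as exc:
        logger.info("metric %s unavailable for %s: %s", key, context, exc)
        return None


def _battery_row(graph_type: str, t: float, g: nx.Graph, is_bipartite: bool,
                 cfg: MetricsConfig) -> dict:
    row: dict = {c: math.nan for c in _TIMELINE_COLUMNS}
    row["graph_type"], row["nd"] = graph_type, t
    ctx = f"{graph_type}@{t:g}"
    row["n_nodes"] = g.number_of_nodes()
    row["n_edges"] = g.number_of_edges()
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        return row
    lcc = largest_component(g)
    row["n_nodes_lcc"] = lcc.number_of_nodes()
    dd = _try("degree_diameter", lambda: degree_diameter(g), ctx)
    if dd:
        row["avg_degree"], row["diameter"] = dd

    mod = _try("modularity", lambda: fast_greedy_modularity(lcc, cfg.weighted_modularity), ctx)
    if mod:
        row["q_max"] = mod.q

    degs = [d for _, d in g.degree() if d > 0]
    pl = _try("power_law", lambda: fit_power_law(
        degs, pvalue_method=cfg.pvalue_method, reps=cfg.bootstrap_reps,
        seed=cfg.seed), ctx)
    if pl:
        row["alpha"], row["xmin"], row["logLik"] = pl.alpha, pl.xmin, pl.logLik
        row["ks_stat"], row["ks_p"] = pl.ks_stat, pl.ks_p

    bt = _try("bartels", lambda: bartels_rank_test(_degree_series_lex(g)), ctx)
    if bt:
        row["bartels_stat"], row["bartels_p"] = bt.statistic, bt.p_value
    er = er_random_graph(lcc.number_of_nodes(), lcc.number_of_edges(),
                         seed=cfg.seed + 1)
    erb = _try("er_bartels", lambda: bartels_rank_test(_degree_series_lex(er)), ctx)
    if erb:
        row["er_bartels_stat"], row["er_bartels_p"] = erb.statistic, erb.p_value

    if not is_bipartite:
        sw = _try("small_world", lambda: small_world(g, cfg.n_rand, cfg.seed), ctx)
        if sw:
            row["c_g"], row["l_g"] = sw.c_g, sw.l_g
            row["c_rand"], row["l_rand"] = sw.c_rand, sw.l_rand
            row["gamma"], row["lambda"], row["s"] = sw.gamma, sw.lam, sw.s
        if cfg.compute_ck:
            ck = _try("ck_scaling", lambda: ck_scaling(g), ctx)
            if ck:
                row["ck_slope"], row["ck_r2"] = ck.slope, ck.r2
    return row


def metrics_timeline(slices: Sequence[BipartiteSlice],
                     cfg: MetricsConfig | None = None) -> pd.DataFrame:
    """Full battery per (graph type × slice threshold).

    ``slices`` are age slices of one bipartite graph, typically at
    t = 0.1, …, 1.0.  Each slice contributes a bipartite row (no
    clustering-based fields) plus a category-projection and an
    enzyme-projection row.  Metric failures (e.g. empty graphs at small
    t) appear as NaN cells with a logged reason.
    """
    from metanet.netbuild import project_one_mode

    cfg = cfg or MetricsConfig()
    rows = []
    for sl in slices:
        rows.append(_battery_row("bipartite", sl.t, sl.graph, True, cfg))
        for side, name in (("category", "category_projection"),
                           ("enzyme", "enzyme_projection")):
            proj = project_one_mode(sl, side)
            rows.append(_battery_row(name, sl.t, proj.graph, False, cfg))
    return pd.DataFrame(rows, columns=_TIMELINE_COLUMNS)
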