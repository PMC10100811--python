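"""Compositionally-aware co-occurrence networks.

Correlations between ASVs are inferred with the SparCC log-ratio variance
approach: for fractions x_i the variation matrix T_ij = var(log(x_i/x_j)) is
decomposed as T_ij ~ w_i + w_j - 2 r_ij sqrt(w_i w_j); assuming sparsity the
basis variances w are solved from the row sums of T, strongly correlated
pairs are iteratively excluded from the basis estimation, and correlations
follow as r_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j)).  Significance is
assessed by permuting each ASV's counts independently across samples (add-one
pseudo p-values).  Thresholded graphs are analyzed for hubs (max degree),
keystones (max betweenness) and dense modules (MCODE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SparCC


@dataclass
class SparccResult:
    correlations: pd.DataFrame
    pvalues: pd.DataFrame | None = None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    excluded_asvs: list[str] = field(default_factory=list)


def _variation_matrix(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """T_ij = var over samples of log(x_i / x_j), from +pseudocount fractions."""
    frac = counts + pseudocount
    frac = frac / frac.sum(axis=1, keepdims=True)
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(T: np.ndarray, exclusion_threshold: float,
                        exclusion_rounds: int):
    """Solve basis variances with iterative exclusion of the strongest pair."""
    d = T.shape[0]
    include = np.ones((d, d), bool)
    np.fill_diagonal(include, False)
    excluded: list[tuple[int, int]] = []
    r = None
    for _ in range(exclusion_rounds + 1):
        n_i = include.sum(axis=1).astype(float)
        M = np.diag(n_i) + include.astype(float)
        t = np.where(include, T, 0.0).sum(axis=1)
        try:
            w = np.linalg.solve(M, t)
        except np.linalg.LinAlgError:
            break
        w = np.maximum(w, 1e-12)
        sw = np.sqrt(w)
        r = (w[:, None] + w[None, :] - T) / (2.0 * np.outer(sw, sw))
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        masked = np.where(include, np.abs(r), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold or len(excluded) >= exclusion_rounds:
            break
        include[i, j] = include[j, i] = False
        excluded.append((min(i, j), max(i, j)))
    return r, excluded


def sparcc(table, n_iterations: int = 20, exclusion_threshold: float = 0.1,
           exclusion_rounds: int = 10, smoothing: str = "pseudocount",
           pseudocount: float = 1.0, seed=None) -> SparccResult:
    """SparCC correlation matrix for an ASV table (or counts DataFrame).

    ``smoothing='pseudocount'`` (default) estimates fractions once from
    counts + 1, giving a deterministic result; ``smoothing='dirichlet'``
    draws ``n_iterations`` Dirichlet resamples of each sample's composition
    and reports the element-wise median correlation.
    """
    counts = table.counts if hasattr(table, "counts") else table
    ids = list(counts.columns)
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("SparCC needs at least 3 ASVs")
    constant = [ids[j] for j in range(x.shape[1])
                if np.allclose(x[:, j], x[0, j])]
    if constant:
        logger.warning("sparcc: excluding constant ASVs: %s", constant)
        keep = [j for j, a in enumerate(ids) if a not in set(constant)]
        x = x[:, keep]
        ids = [ids[j] for j in keep]
        if x.shape[1] < 3:
            raise ValueError("SparCC needs at least 3 non-constant ASVs")
    if smoothing == "pseudocount":
        T = _variation_matrix(x, pseudocount)
        r, excl = _basis_correlations(T, exclusion_threshold, exclusion_rounds)
    elif smoothing == "dirichlet":
        rng = np.random.default_rng(seed)
        rs = []
        excl = []
        for _ in range(n_iterations):
            frac = np.vstack([rng.dirichlet(row + pseudocount) for row in x])
            logf = np.log(frac)
            cov = np.cov(logf, rowvar=False)
            v = np.diag(cov)
            T = v[:, None] + v[None, :] - 2.0 * cov
            ri, ei = _basis_correlations(T, exclusion_threshold, exclusion_rounds)
            rs.append(ri)
            excl = ei
        r = np.median(np.stack(rs), axis=0)
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    corr = pd.DataFrame(r, index=ids, columns=ids)
    pairs = [(ids[i], ids[j]) for i, j in excl]
    return SparccResult(corr, excluded_pairs=pairs, excluded_asvs=constant)


def sparcc_pvalues(table, observed: SparccResult, n_boot: int = 100,
                   seed=None, **sparcc_kwargs) -> pd.DataFrame:
    """Two-sided pseudo p-values by independent per-ASV permutation.

    Each resample shuffles every ASV's counts independently across samples
    (destroying correlation, preserving marginals); p = (#{|r*| >= |r|} + 1)
    / (n_boot + 1), so the smallest attainable p is 1/(n_boot+1).
    """
    counts = table.counts if hasattr(table, "counts") else table
    ids = list(observed.correlations.columns)
    x = counts[ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    r_obs = np.abs(observed.correlations.to_numpy())
    hits = np.zeros_like(r_obs)
    n, d = x.shape
    for _ in range(n_boot):
        perm = np.empty_like(x)
        for j in range(d):
            perm[:, j] = x[rng.permutation(n), j]
        res = sparcc(pd.DataFrame(perm, columns=ids), **sparcc_kwargs)
        hits += np.abs(res.correlations.to_numpy()) >= r_obs
    p = (hits + 1.0) / (n_boot + 1.0)
    np.fill_diagonal(p, 1.0)
    pdf = pd.DataFrame(p, index=ids, columns=ids)
    observed.pvalues = pdf
    return pdf


# ---------------------------------------------------------------------------
# Network construction and statistics


def build_network(result: SparccResult, node_meta: pd.DataFrame | None = None,
                  prevalence: pd.Series | None = None,
                  r_threshold: float = 0.5, p_threshold: float = 0.01,
                  prevalence_min: float = 0.20,
                  drop_isolated: bool = True) -> nx.Graph:
    """Threshold the SparCC result into an undirected co-occurrence graph.

    Edges require |r| strictly greater than ``r_threshold`` and p strictly
    below ``p_threshold``; nodes require prevalence strictly above
    ``prevalence_min`` when a prevalence series is given.  Node attributes
    (mean abundance, family, heritable flag) are taken from ``node_meta``.
    """
    if not (0 <= r_threshold <= 1 and 0 < p_threshold <= 1):
        raise ValueError("invalid thresholds")
    corr = result.correlations
    ids = list(corr.columns)
    if prevalence is not None:
        ids = [a for a in ids if prevalence.get(a, 0.0) > prevalence_min]
    g = nx.Graph()
    for a in ids:
        attrs = {}
        if node_meta is not None and a in node_meta.index:
            attrs = node_meta.loc[a].to_dict()
        g.add_node(a, **attrs)
    p = result.pvalues
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r = float(corr.loc[a, b])
            pv = float(p.loc[a, b]) if p is not None else 0.0
            if abs(r) > r_threshold and pv < p_threshold:
                g.add_edge(a, b, r=r, p=pv, sign=1 if r > 0 else -1)
    if drop_isolated:
        g.remove_nodes_from([v for v in g if g.degree(v) == 0])
    return g


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    average_degree: float
    density: float
    degree: dict
    betweenness: dict
    hubs: list
    keystones: list


def network_stats(g: nx.Graph) -> NetworkStats:
    """Whole-graph metrics plus hub (max degree) and keystone (max
    betweenness) calls; ties share the call and are all reported,
    ordered lexicographically."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n = g.number_of_nodes()
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    if n == 1:
        node = next(iter(g))
        return NetworkStats(1, 0, 0.0, 0.0, 0.0, deg, btw, [node], [node])
    cc = nx.average_clustering(g)
    avg_deg = 2.0 * g.number_of_edges() / n
    density = nx.density(g)
    max_deg = max(deg.values())
    hubs = sorted([v for v, d in deg.items() if d == max_deg])
    max_btw = max(btw.values())
    keystones = sorted([v for v, b in btw.items() if abs(b - max_btw) < 1e-12])
    if len(hubs) > 1 or len(keystones) > 1:
        logger.info("network_stats: ties — hubs=%s keystones=%s", hubs, keystones)
    return NetworkStats(n, g.number_of_edges(), cc, avg_deg, density,
                        deg, btw, hubs, keystones)


# ---------------------------------------------------------------------------
# MCODE


def _highest_kcore(g: nx.Graph) -> tuple[nx.Graph, int]:
    """The non-empty k-core of g with maximal k (k=0 core is g itself)."""
    core_num = nx.core_number(g)
    k = max(core_num.values())
    nodes = [v for v, c in core_num.items() if c >= k]
    return g.subgraph(nodes), k


def _mcode_weights(g: nx.Graph) -> dict:
    """MCODE node weight: density of the highest k-core of the closed
    neighborhood, times that core's k."""
    w = {}
    for v in g:
        nbrs = list(g.neighbors(v)) + [v]
        sub = g.subgraph(nbrs)
        if sub.number_of_edges() == 0:
            w[v] = 0.0
            continue
        core, k = _highest_kcore(sub)
        w[v] = k * nx.density(core)
    return w


@dataclass
class McodeCluster:
    nodes: list
    score: float
    seed: object


def mcode(g: nx.Graph, node_score_cutoff: float = 0.2, k_core: int = 2,
          max_depth: int = 100) -> list[McodeCluster]:
    """Dense-module detection (molecular complex detection).

    Stage 1 weights nodes by core-clustering coefficient x core number;
    stage 2 grows complexes from the highest-weight unseen seed, including
    neighbors whose weight is within ``node_score_cutoff`` of the seed's;
    stage 3 discards complexes lacking a ``k_core``-core.  Cluster score is
    density x size; clusters are returned in descending score order.
    """
    if g.number_of_nodes() == 0:
        return []
    weights = _mcode_weights(g)
    seen: set = set()
    clusters = []
    for seed in sorted(weights, key=lambda v: (-weights[v], str(v))):
        if seed in seen:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in g.neighbors(v):
                    if u in seen or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        seen |= members
        sub = g.subgraph(members)
        if sub.number_of_nodes() < 2:
            continue
        core_num = nx.core_number(nx.Graph(sub))
        if max(core_num.values()) < k_core:
            continue
        score = nx.density(sub) * sub.number_of_nodes()
        clusters.append(McodeCluster(sorted(sub.nodes), float(score), seed))
    clusters.sort(key=lambda c: (-c.score, c.nodes))
    return clusters


# ---------------------------------------------------------------------------
# Export


def export_graphml(g: nx.Graph, path) -> None:
    h = nx.Graph()
    for v, attrs in g.nodes(data=True):
        h.add_node(v, **{k: ("" if pd.isna(val) else val)
                         for k, val in attrs.items()})
    for u, v, attrs in g.edges(data=True):
        h.add_edge(u, v, **attrs)
    nx.write_graphml(h, path)


def export_edgelist(g: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
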