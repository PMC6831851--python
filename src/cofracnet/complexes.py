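"""Protein complex discovery on ΣLLS-weighted networks.

Three deterministic algorithms, each returning member sets of size >= 2
(heterodimers are legitimate complexes):

* **mcl_cluster** -- Markov clustering: alternate expansion (matrix power)
  and inflation (elementwise power + column renormalization) of the
  column-stochastic transition matrix until convergence; clusters are read
  off the attractor structure of the limit matrix.
* **cohesiveness_grow** -- ClusterONE-style greedy seed growth maximizing
  the cohesiveness f(S) = w_in / (w_in + w_bound + penalty); highly
  overlapping grown sets (ω >= overlap_merge) are merged.
* **core_attach** -- core-attachment: dense cores grown greedily from
  top-weight edges (induced edge density >= core_density), plus attachment
  proteins adjacent to at least attach_ratio of a core's members.

Predictions are matched to a reference catalog by the overlap score
ω(A, B) = |A∩B|² / (|A|·|B|), with ω >= 0.25 the conventional recovery
cutoff.  Tie-breaking is lexicographic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu, pearsonr

from .enrichment import hypergeom_p
from .io import ReferenceComplexCatalog

__all__ = [
    "PredictedComplex",
    "omega",
    "mcl_cluster",
    "cohesiveness_grow",
    "core_attach",
    "match_and_select",
    "interaction_profile_correlation",
    "within_between_test",
    "network_graph",
]


@dataclass
class PredictedComplex:
    members: frozenset[str]
    algorithm: str
    internal_score: float = float("nan")
    best_match: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a predicted complex needs >= 2 members")


def network_graph(edges, weight_col: str = "sigma_lls") -> nx.Graph:
    """Build a weighted graph from a StaticNetwork or an edge DataFrame."""
    df = getattr(edges, "edges", edges)
    g = nx.Graph()
    for a, b, w in zip(df["protein_a"], df["protein_b"], df[weight_col]):
        g.add_edge(a, b, weight=float(w))
    return g


def omega(a: set, b: set) -> float:
    """Overlap score |a∩b|² / (|a|·|b|), in [0, 1]."""
    if not a or not b:
        raise ValueError("omega is undefined for empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-6,
    self_loops: float = 1.0,
) -> list[PredictedComplex]:
    """Markov clustering of a weighted graph (edge weight = ΣLLS)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    np.fill_diagonal(m, self_loops)
    m /= m.sum(axis=0, keepdims=True)

    trace = []
    for it in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        delta = float(np.abs(m - prev).max())
        trace.append(delta)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations; residual trace tail: "
            f"{[f'{d:.2e}' for d in trace[-5:]]}"
        )

    # attractor rows with support define clusters; overlapping ones merge
    raw: list[set[int]] = []
    for i in range(n):
        if m[i, i] > 0:
            raw.append(set(np.nonzero(m[i, :] > 0)[0].tolist()))
    merged: list[set[int]] = []
    for cluster in raw:
        hits = [c for c in merged if c & cluster]
        for c in hits:
            merged.remove(c)
            cluster |= c
        merged.append(cluster)

    out = []
    for cluster in merged:
        members = frozenset(nodes[i] for i in cluster)
        if len(members) < 2:
            continue
        out.append(
            PredictedComplex(
                members=members, algorithm="mcl", internal_score=_mean_internal(graph, members)
            )
        )
    return sorted(out, key=lambda c: sorted(c.members))


def _mean_internal(graph: nx.Graph, members: frozenset[str]) -> float:
    weights = [
        d["weight"] for a, b, d in graph.subgraph(members).edges(data=True)
    ]
    return float(np.mean(weights)) if weights else 0.0


# ---------------------------------------------------------------------------
# cohesiveness growth (ClusterONE-style)


def cohesiveness(graph: nx.Graph, members: set[str], penalty: float = 2.0) -> float:
    """f(S) = w_in / (w_in + w_bound + penalty)."""
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    w_in = 0.0
    w_bound = 0.0
    members = set(members)
    for v in members:
        for u, data in graph[v].items():
            w = float(data.get("weight", 1.0))
            if u in members:
                w_in += w / 2.0
            else:
                w_bound += w
    denom = w_in + w_bound + penalty
    return w_in / denom if denom > 0 else 0.0


def cohesiveness_grow(
    graph: nx.Graph,
    penalty: float = 2.0,
    overlap_merge: float = 0.8,
    min_size: int = 2,
) -> list[PredictedComplex]:
    """Greedy seed-and-grow maximization of cohesiveness.

    Seeds are taken in decreasing weighted-degree order (lexicographic on
    ties), skipping nodes already covered by a grown set.  At each step the
    single best addition of a boundary node or removal of a member is
    applied while it strictly improves f(S).
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    wdeg = {v: sum(d.get("weight", 1.0) for d in graph[v].values()) for v in graph.nodes}
    seeds = sorted(graph.nodes, key=lambda v: (-wdeg[v], v))
    covered: set[str] = set()
    grown: list[set[str]] = []

    for seed in seeds:
        if seed in covered:
            continue
        members = {seed}
        f = cohesiveness(graph, members, penalty)
        while True:
            boundary = {u for v in members for u in graph[v]} - members
            best_f, best_move = f, None
            for u in sorted(boundary):
                cand = members | {u}
                fu = cohesiveness(graph, cand, penalty)
                if fu > best_f:
                    best_f, best_move = fu, ("add", u)
            for u in sorted(members - {seed}):
                cand = members - {u}
                fu = cohesiveness(graph, cand, penalty) if cand else 0.0
                if fu > best_f:
                    best_f, best_move = fu, ("del", u)
            if best_move is None:
                break
            op, u = best_move
            members = members | {u} if op == "add" else members - {u}
            f = best_f
        grown.append(members)
        covered |= members

    # merge heavily overlapping sets (ω >= overlap_merge), to a fixed point
    changed = True
    while changed:
        changed = False
        merged: list[set[str]] = []
        for s in sorted(grown, key=lambda s: sorted(s)):
            hit = None
            for t in merged:
                if omega(s, t) >= overlap_merge:
                    hit = t
                    break
            if hit is not None:
                hit |= s
                changed = True
            else:
                merged.append(set(s))
        grown = merged

    out = [
        PredictedComplex(
            members=frozenset(s),
            algorithm="cohesiveness",
            internal_score=cohesiveness(graph, s, penalty),
        )
        for s in grown
        if len(s) >= min_size
    ]
    return sorted(out, key=lambda c: sorted(c.members))


# ---------------------------------------------------------------------------
# core-attachment


def _density(graph: nx.Graph, members: set[str]) -> float:
    k = len(members)
    if k < 2:
        return 1.0
    e = graph.subgraph(members).number_of_edges()
    return e / (k * (k - 1) / 2)


def core_attach(
    graph: nx.Graph,
    core_density: float = 0.7,
    attach_ratio: float = 0.5,
) -> list[PredictedComplex]:
    """Density cores grown greedily from top-weight edges, plus attachments.

    A core starts from the heaviest untouched edge and greedily absorbs the
    neighbor with the largest total weight to the core while the induced
    (unweighted) edge density stays >= core_density.  Attachments are
    outside proteins adjacent to >= attach_ratio of the core's members.
    """
    for name, value in (("core_density", core_density), ("attach_ratio", attach_ratio)):
        if not 0.0 < value <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    edges = sorted(
        graph.edges(data=True),
        key=lambda e: (-float(e[2].get("weight", 1.0)), tuple(sorted((e[0], e[1])))),
    )
    in_core: set[str] = set()
    cores: list[set[str]] = []
    for a, b, _ in edges:
        if a in in_core or b in in_core:
            continue
        core = {a, b}
        while True:
            neigh = {u for v in core for u in graph[v]} - core - in_core
            best = None
            for u in sorted(neigh):
                if _density(graph, core | {u}) < core_density:
                    continue
                w_to_core = sum(
                    float(graph[u][v].get("weight", 1.0)) for v in core if graph.has_edge(u, v)
                )
                if best is None or w_to_core > best[0]:
                    best = (w_to_core, u)
            if best is None:
                break
            core.add(best[1])
        cores.append(core)
        in_core |= core

    out = []
    for core in cores:
        attachments = set()
        for u in set(graph.nodes) - core:
            links = sum(1 for v in core if graph.has_edge(u, v))
            if links / len(core) >= attach_ratio:
                attachments.add(u)
        members = frozenset(core | attachments)
        if len(members) < 2:
            continue
        out.append(
            PredictedComplex(
                members=members,
                algorithm="core_attach",
                internal_score=_mean_internal(graph, members),
            )
        )
    # dedupe identical member sets
    seen: dict[frozenset, PredictedComplex] = {}
    for c in out:
        seen.setdefault(c.members, c)
    return sorted(seen.values(), key=lambda c: sorted(c.members))


# ---------------------------------------------------------------------------
# matching and benchmarking


def match_and_select(
    predictions: dict[str, list[PredictedComplex]],
    catalog: ReferenceComplexCatalog,
    omega_cutoff: float = 0.25,
) -> tuple[dict[str, list[PredictedComplex]], str, dict[str, float]]:
    """Match every prediction to its best reference complex and pick the
    algorithm whose predictions are most enriched for recovery.

    Each prediction gets ``best_match = (reference id, ω)``; it counts as
    recovered if ω >= omega_cutoff.  The per-algorithm hypergeometric p
    treats the pooled predictions of all algorithms as the population
    (K = pooled recovered, n = this algorithm's predictions, k = its
    recovered); the best algorithm has the smallest p, ties broken by
    recovery rate then name.
    """
    if not catalog.complexes:
        raise ValueError("empty reference catalog")
    if not predictions:
        raise ValueError("no predictions supplied")
    recovered_by_alg: dict[str, int] = {}
    for alg, preds in predictions.items():
        count = 0
        for pred in preds:
            best: tuple[float, str] | None = None
            for cid in sorted(catalog.complexes):
                om = omega(pred.members, catalog.complexes[cid])
                if best is None or om > best[0]:
                    best = (om, cid)
            pred.best_match = (best[1], best[0]) if best else None
            if best and best[0] >= omega_cutoff:
                count += 1
        recovered_by_alg[alg] = count

    total = sum(len(p) for p in predictions.values())
    total_recovered = sum(recovered_by_alg.values())
    pvals: dict[str, float] = {}
    for alg in sorted(predictions):
        n = len(predictions[alg])
        k = recovered_by_alg[alg]
        pvals[alg] = hypergeom_p(k, total_recovered, n, total) if n else 1.0
    best_alg = min(
        sorted(predictions),
        key=lambda a: (
            pvals[a],
            -(recovered_by_alg[a] / len(predictions[a]) if predictions[a] else 0.0),
            a,
        ),
    )
    return predictions, best_alg, pvals


def interaction_profile_correlation(graph: nx.Graph, pair: tuple[str, str]) -> float | None:
    """Pearson correlation of two proteins' edge-weight vectors.

    Vectors run over all other nodes (self and the mutual edge excluded;
    absent edges count 0).  Returns None when a vector has zero variance.
    """
    a, b = pair
    if a not in graph or b not in graph:
        raise ValueError(f"pair {pair} not in network")
    others = sorted(set(graph.nodes) - {a, b})
    if len(others) < 2:
        return None
    va = np.array([float(graph[a][v]["weight"]) if graph.has_edge(a, v) else 0.0 for v in others])
    vb = np.array([float(graph[b][v]["weight"]) if graph.has_edge(b, v) else 0.0 for v in others])
    if va.std() == 0 or vb.std() == 0:
        return None
    return float(pearsonr(va, vb)[0])


def within_between_test(r_within, r_between) -> float:
    """One-sided rank-sum p that within-complex correlations exceed
    between-complex correlations."""
    r_within = list(r_within)
    r_between = list(r_between)
    if not r_within or not r_between:
        raise ValueError("both samples must be non-empty")
    return float(mannwhitneyu(r_within, r_between, alternative="greater").pvalue)
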