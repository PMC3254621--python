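"""High-confidence PPIN filtering and cross-locus prioritization (extended SPAN).

A STRING-style detailed-links table is reduced to a high-confidence,
non-literature network (combined score strictly above 800 and at least one
of the gene-fusion / experimental / curated-database channels positive).
Candidate proteins from the two linked chromosomal windows are then scored
against a degree-preserving null: each randomized network is drawn by
double-edge swaps that conserve every protein's number of interactions, and

* the **node** statistic is a protein's number of cross-locus interactions
  (edges to the opposite window's candidate set);
* the **edge** statistic (the extension) is the occurrence of one specific
  cross-locus interaction.

Empirical p-values use the (r + 1) / (N + 1) pseudocount estimator, so they
are never exactly zero, and node and edge families are Benjamini-Hochberg
adjusted separately. Randomization is applied to the *full* filtered
network, so null cross-locus counts reflect genome-wide degree structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

STRING_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)
DEFAULT_MIN_COMBINED = 800
DEFAULT_REQUIRED_CHANNELS = ("fusion", "experimental", "database")

TIER_STRONG, TIER_WEAK, TIER_BACKGROUND = "strong", "weak", "background"


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateSets:
    """Disjoint protein sets from the two linked chromosomal windows."""

    set_a: frozenset
    set_b: frozenset

    def __init__(self, set_a, set_b):
        object.__setattr__(self, "set_a", frozenset(set_a))
        object.__setattr__(self, "set_b", frozenset(set_b))
        if self.set_a & self.set_b:
            raise NetworkError("candidate sets must be disjoint")


@dataclass(frozen=True)
class PrioritizationResult:
    """Node- and edge-level empirical p/q values for the candidate sets.

    ``nodes`` columns: protein, candidate_set, observed_cross_degree,
    p_value, q_value, tier. ``edges`` columns: protein_a, protein_b,
    p_value, q_value, tier (observed cross-locus edges only).
    ``strong_edges`` lists edges where the edge *and both endpoints* pass
    the strong FDR tier — the headline subnetworks.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    n_randomizations: int
    seed: int
    fdr_strong: float = 1e-4
    fdr_weak: float = 0.5
    strong_edges: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# STRING filtering
# ---------------------------------------------------------------------------

def filter_string_edges(
    records: pd.DataFrame,
    min_combined: int = DEFAULT_MIN_COMBINED,
    required_channels: tuple[str, ...] = DEFAULT_REQUIRED_CHANNELS,
) -> nx.Graph:
    """High-confidence non-literature network from detailed-links records.

    An edge is retained iff combined_score > ``min_combined`` (strict) and
    at least one ``required_channels`` score is positive; with the defaults
    this keeps highly reliable interactions supported by gene fusion,
    experimental, or curated-database evidence and drops purely
    literature-mined (textmining) ones. Duplicate A-B / B-A records are
    merged channel-wise by maximum; self-loops are dropped with a warning.
    """
    for col in ("protein1", "protein2", "combined_score"):
        if col not in records.columns:
            raise NetworkError(f"records missing column {col!r}")
    for ch in required_channels:
        if ch not in STRING_CHANNELS:
            raise NetworkError(f"unknown evidence channel {ch!r}")
    channels = [c for c in STRING_CHANNELS if c in records.columns]
    graph = nx.Graph()
    n_self = 0
    for rec in records.itertuples(index=False):
        u, v = str(rec.protein1), str(rec.protein2)
        if u == v:
            n_self += 1
            continue
        attrs = {c: int(getattr(rec, c, 0)) for c in channels}
        attrs["combined_score"] = int(rec.combined_score)
        if graph.has_edge(u, v):  # merge duplicate orientations by max
            old = graph.edges[u, v]
            for k, x in attrs.items():
                old[k] = max(old.get(k, 0), x)
        else:
            graph.add_edge(u, v, **attrs)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop record(s)", stacklevel=2)
    drop = [
        (u, v)
        for u, v, d in graph.edges(data=True)
        if d["combined_score"] <= min_combined
        or not any(d.get(c, 0) > 0 for c in required_channels)
    ]
    graph.remove_edges_from(drop)
    graph.remove_nodes_from([n for n in list(graph) if graph.degree[n] == 0])
    return graph


def cross_locus_subgraph(
    ppin: nx.Graph, sets: CandidateSets
) -> list[tuple[str, str]]:
    """Edges with one endpoint in each candidate set (within-set edges excluded).

    Returned as a deterministically sorted list of (set_a protein,
    set_b protein) pairs.
    """
    out = []
    for u, v in ppin.edges():
        if u in sets.set_a and v in sets.set_b:
            out.append((u, v))
        elif v in sets.set_a and u in sets.set_b:
            out.append((v, u))
    return sorted(out)


# ---------------------------------------------------------------------------
# degree-preserving randomization
# ---------------------------------------------------------------------------

def _edge_arrays(ppin: nx.Graph):
    nodes = sorted(ppin.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array(
        sorted((min(index[u], index[v]), max(index[u], index[v])) for u, v in ppin.edges()),
        dtype=np.int64,
    ).reshape(-1, 2)
    return nodes, index, edges


def _double_edge_swap(
    edges: np.ndarray, n_nodes: int, n_attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, set]:
    """Run ``n_attempts`` attempted double-edge swaps on a copy of ``edges``.

    A swap draws two distinct edges (u, v), (x, y), optionally reverses the
    second, and proposes (u, x), (v, y); proposals creating a self-loop or
    duplicate edge are rejected (the chain stays put), which leaves the
    uniform distribution over simple graphs with this degree sequence
    invariant. Returns the edge array and its set of (lo, hi) keys.
    """
    e = edges.copy()
    n_edges = len(e)
    edge_set = {(int(a), int(b)) for a, b in e}
    if n_edges < 2:
        return e, edge_set
    idx1 = rng.integers(0, n_edges, size=n_attempts)
    idx2 = rng.integers(0, n_edges, size=n_attempts)
    flips = rng.integers(0, 2, size=n_attempts)
    for k in range(n_attempts):
        i, j = idx1[k], idx2[k]
        if i == j:
            continue
        u, v = e[i]
        x, y = e[j]
        if flips[k]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y:
            continue
        a1, b1 = (u, x) if u < x else (x, u)
        a2, b2 = (v, y) if v < y else (y, v)
        if (a1, b1) in edge_set or (a2, b2) in edge_set:
            continue
        edge_set.discard((min(u, v), max(u, v)))
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add((a1, b1))
        edge_set.add((a2, b2))
        e[i] = (a1, b1)
        e[j] = (a2, b2)
    return e, edge_set


def randomize_network(
    ppin: nx.Graph, swaps_per_edge: int = 10, seed: int = 0
) -> nx.Graph:
    """One degree-preserving randomization of the network.

    Performs ``swaps_per_edge * n_edges`` attempted double-edge swaps from
    the observed network; every node keeps its exact degree and the graph
    stays simple. Edge evidence scores are not propagated (they are
    meaningless on a null network). Deterministic given ``seed``; graphs
    with no valid swap (e.g. a triangle) come back identical.
    """
    if swaps_per_edge < 1:
        raise NetworkError("swaps_per_edge must be positive")
    nodes, _, edges = _edge_arrays(ppin)
    rng = np.random.default_rng(seed)
    e, _ = _double_edge_swap(edges, len(nodes), swaps_per_edge * len(edges), rng)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[a], nodes[b]) for a, b in e)
    return out


def _cross_null_counts(
    ppin: nx.Graph,
    sets: CandidateSets,
    n_rand: int,
    swaps_per_edge: int,
    seed: int,
):
    """Null exceedance counts for node cross-degrees and edge occurrences.

    Each of ``n_rand`` randomizations is drawn independently (fresh
    double-edge-swap burn-in from the observed network, per-sample seeds
    spawned from ``seed``). Returns (proteins, observed cross-degrees,
    node exceedance counts, observed cross edges, edge occurrence counts).
    """
    nodes, index, edges = _edge_arrays(ppin)
    n = len(nodes)
    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)
    for p in sets.set_a:
        if p in index:
            in_a[index[p]] = True
    for p in sets.set_b:
        if p in index:
            in_b[index[p]] = True

    def cross_degrees(eu: np.ndarray, ev: np.ndarray) -> np.ndarray:
        m1 = in_a[eu] & in_b[ev]
        m2 = in_a[ev] & in_b[eu]
        ends = np.concatenate([eu[m1], ev[m1], eu[m2], ev[m2]])
        return np.bincount(ends, minlength=n)

    obs_cd = cross_degrees(edges[:, 0], edges[:, 1]) if len(edges) else np.zeros(n, int)
    obs_edges = cross_locus_subgraph(ppin, sets)
    obs_edge_keys = [
        (min(index[u], index[v]), max(index[u], index[v])) for u, v in obs_edges
    ]

    candidates = sorted((sets.set_a | sets.set_b) & set(nodes))
    cand_idx = np.array([index[p] for p in candidates], dtype=int)
    node_exceed = np.zeros(len(candidates), dtype=int)
    edge_count = np.zeros(len(obs_edge_keys), dtype=int)

    n_attempts = swaps_per_edge * len(edges)
    child_seeds = np.random.SeedSequence(seed).spawn(n_rand)
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        e, edge_set = _double_edge_swap(edges, n, n_attempts, rng)
        cd = cross_degrees(e[:, 0], e[:, 1])
        node_exceed += (cd[cand_idx] >= obs_cd[cand_idx]).astype(int)
        for k, key in enumerate(obs_edge_keys):
            if key in edge_set:
                edge_count[k] += 1
    return candidates, obs_cd[cand_idx] if len(candidates) else np.zeros(0, int), \
        node_exceed, obs_edges, edge_count


def _pseudo_p(r: np.ndarray, n_rand: int) -> np.ndarray:
    return (np.asarray(r, dtype=float) + 1.0) / (n_rand + 1.0)


def node_priority(
    ppin: nx.Graph,
    sets: CandidateSets,
    n_rand: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical node p-values for cross-locus connectivity.

    For each candidate protein, p = (r + 1) / (n_rand + 1) where r counts
    randomized networks in which its cross-locus degree is at least the
    observed one. Candidate proteins absent from the network get observed
    degree 0 and p = 1.
    """
    if n_rand < 10:
        raise NetworkError("n_rand must be >= 10")
    candidates, obs, exceed, _, _ = _cross_null_counts(
        ppin, sets, n_rand, swaps_per_edge, seed
    )
    rows = {p: (int(o), _pseudo_p(r, n_rand)) for p, o, r in zip(candidates, obs, exceed)}
    out = []
    for p in sorted(sets.set_a | sets.set_b):
        o, pv = rows.get(p, (0, 1.0))
        out.append(
            (p, "a" if p in sets.set_a else "b", o, float(pv))
        )
    return pd.DataFrame(
        out, columns=["protein", "candidate_set", "observed_cross_degree", "p_value"]
    )


def edge_priority(
    ppin: nx.Graph,
    sets: CandidateSets,
    n_rand: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p-values for each observed cross-locus interaction.

    p = (r + 1) / (n_rand + 1) where r counts randomized networks that
    contain that specific edge; a small p means the interaction is unlikely
    under the degree-preserving null.
    """
    if n_rand < 10:
        raise NetworkError("n_rand must be >= 10")
    _, _, _, obs_edges, edge_count = _cross_null_counts(
        ppin, sets, n_rand, swaps_per_edge, seed
    )
    return pd.DataFrame(
        {
            "protein_a": [u for u, _ in obs_edges],
            "protein_b": [v for _, v in obs_edges],
            "p_value": _pseudo_p(edge_count, n_rand),
        }
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (ties share a q, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise NetworkError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier(q: np.ndarray, fdr_strong: float, fdr_weak: float) -> np.ndarray:
    return np.where(
        q < fdr_strong, TIER_STRONG, np.where(q < fdr_weak, TIER_WEAK, TIER_BACKGROUND)
    )


def prioritize(
    ppin: nx.Graph,
    sets: CandidateSets,
    fdr_strong: float = 1e-4,
    fdr_weak: float = 0.5,
    n_rand: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> PrioritizationResult:
    """Full cross-locus prioritization: p-values, FDR tiers, headline edges.

    Node and edge statistics are evaluated on one shared set of
    randomizations; their p-value families are BH-adjusted separately and
    cut into ``strong`` (q < fdr_strong), ``weak`` (q < fdr_weak) and
    ``background`` tiers. ``strong_edges`` lists the edges for which the
    edge *and both endpoint nodes* are strong — the reported subnetworks.
    """
    if n_rand < 10:
        raise NetworkError("n_rand must be >= 10")
    candidates, obs, exceed, obs_edges, edge_count = _cross_null_counts(
        ppin, sets, n_rand, swaps_per_edge, seed
    )
    present = {p: (int(o), int(r)) for p, o, r in zip(candidates, obs, exceed)}
    all_proteins = sorted(sets.set_a | sets.set_b)
    node_obs = np.array([present.get(p, (0, n_rand))[0] for p in all_proteins])
    node_r = np.array([present.get(p, (0, n_rand))[1] for p in all_proteins])
    node_p = _pseudo_p(node_r, n_rand)
    node_q = fdr_adjust(node_p)
    nodes = pd.DataFrame(
        {
            "protein": all_proteins,
            "candidate_set": ["a" if p in sets.set_a else "b" for p in all_proteins],
            "observed_cross_degree": node_obs,
            "p_value": node_p,
            "q_value": node_q,
            "tier": _tier(node_q, fdr_strong, fdr_weak),
        }
    )
    edge_p = _pseudo_p(edge_count, n_rand)
    edge_q = fdr_adjust(edge_p)
    edges = pd.DataFrame(
        {
            "protein_a": [u for u, _ in obs_edges],
            "protein_b": [v for _, v in obs_edges],
            "p_value": edge_p,
            "q_value": edge_q,
            "tier": _tier(edge_q, fdr_strong, fdr_weak) if len(obs_edges) else [],
        }
    )
    strong_nodes = set(nodes.loc[nodes["tier"] == TIER_STRONG, "protein"])
    strong = tuple(
        (u, v)
        for (u, v), t in zip(obs_edges, edges["tier"] if len(edges) else [])
        if t == TIER_STRONG and u in strong_nodes and v in strong_nodes
    )
    return PrioritizationResult(
        nodes=nodes,
        edges=edges,
        n_randomizations=n_rand,
        seed=seed,
        fdr_strong=fdr_strong,
        fdr_weak=fdr_weak,
        strong_edges=strong,
    )


def tiered_graph(result: PrioritizationResult, ppin: nx.Graph) -> nx.Graph:
    """Cytoscape-ready display graph of every observed cross-locus edge.

    Nodes and edges carry their p/q values and display tier (strong tiers
    render large/thick, background small/thin).
    """
    g = nx.Graph()
    for rec in result.nodes.itertuples(index=False):
        g.add_node(
            rec.protein,
            candidate_set=rec.candidate_set,
            observed_cross_degree=int(rec.observed_cross_degree),
            p_value=float(rec.p_value),
            q_value=float(rec.q_value),
            tier=rec.tier,
        )
    for rec in result.edges.itertuples(index=False):
        attrs = dict(
            p_value=float(rec.p_value), q_value=float(rec.q_value), tier=rec.tier
        )
        if ppin.has_edge(rec.protein_a, rec.protein_b):
            attrs["combined_score"] = int(
                ppin.edges[rec.protein_a, rec.protein_b].get("combined_score", 0)
            )
        g.add_edge(rec.protein_a, rec.protein_b, **attrs)
    return g
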