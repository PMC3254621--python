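"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: least-squares
residuals come from explicitly built design matrices, the non-recombinant
span from a brute-force run search, overlap queries from a linear scan,
degree-preserving null distributions from exhaustive graph enumeration,
and BH q-values from the step-up definition written out by hand.
"""

from __future__ import annotations

import itertools

import numpy as np


def rss_lstsq(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def lod_one_marker(geno: np.ndarray, y: np.ndarray) -> float:
    """Single-marker genotype-class-means LOD on complete cases."""
    ok = geno >= 0
    yy, gg = y[ok], geno[ok]
    classes = np.unique(gg)
    if len(classes) < 2:
        return 0.0
    n = ok.sum()
    rss0 = rss_lstsq(np.ones((n, 1)), yy)
    rss1 = rss_lstsq((gg[:, None] == classes[None, :]).astype(float), yy)
    if rss1 <= 1e-12 * max(rss0, 1.0):
        return np.inf
    return 0.5 * n * np.log10(rss0 / rss1)


def lods_two_marker(gi: np.ndarray, gj: np.ndarray, y: np.ndarray):
    """(lod_full, lod_add, lod_int) from explicit design matrices."""
    ok = (gi >= 0) & (gj >= 0)
    yy, a, b = y[ok], gi[ok], gj[ok]
    n = int(ok.sum())
    joint = a * 3 + b
    classes = np.unique(joint)
    rss0 = rss_lstsq(np.ones((n, 1)), yy)
    rss_full = rss_lstsq((joint[:, None] == classes[None, :]).astype(float), yy)
    design_add = np.column_stack(
        [np.ones(n), a == 1, a == 2, b == 1, b == 2]
    ).astype(float)
    rss_add = rss_lstsq(design_add, yy)
    scale = max(rss0, 1.0)

    def lod(r0, r1):
        if r1 <= 1e-12 * scale:
            return np.inf
        return 0.5 * n * np.log10(r0 / r1)

    return lod(rss0, rss_full), lod(rss0, rss_add), lod(rss_add, rss_full)


def brute_force_span(compatible: np.ndarray, peak: int) -> tuple[int, int]:
    """Longest contiguous run of all-True columns containing ``peak``.

    ``compatible`` is (mice x markers) booleans (AA-or-missing).
    """
    ok = compatible.all(axis=0)
    assert ok[peak]
    lo = peak
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return lo, hi


def genes_overlapping(annotation, chrom: str, start: int, end: int) -> set:
    """Linear-scan any-overlap query on a 1-based inclusive annotation."""
    hits = set()
    for rec in annotation.itertuples(index=False):
        if (
            str(rec.chromosome) == str(chrom)
            and rec.start_bp <= end
            and rec.end_bp >= start
        ):
            hits.add(rec.gene_id)
    return hits


def enumerate_degree_preserving_graphs(nodes: list, edges: set):
    """All simple graphs on ``nodes`` with the degree sequence of ``edges``.

    Brute force over edge subsets of the complete graph; feasible for
    <= 6 nodes. Edges are frozensets of node pairs.
    """
    deg = {v: 0 for v in nodes}
    for e in edges:
        for v in e:
            deg[v] += 1
    all_pairs = [frozenset(p) for p in itertools.combinations(nodes, 2)]
    out = []
    for subset in itertools.combinations(all_pairs, len(edges)):
        d = {v: 0 for v in nodes}
        for e in subset:
            for v in e:
                d[v] += 1
        if d == deg:
            out.append(set(subset))
    return out


def exact_null_probs(nodes, edges, set_a, set_b):
    """Exact uniform-null P(cross-degree >= observed) per candidate node and
    P(edge present) per observed cross edge."""
    graphs = enumerate_degree_preserving_graphs(nodes, edges)

    def cross_degree(graph, v):
        other = set_b if v in set_a else set_a
        return sum(1 for e in graph if v in e and (set(e) - {v}) & other)

    obs = {v: cross_degree(edges, v) for v in set_a | set_b}
    node_p = {
        v: np.mean([cross_degree(g, v) >= obs[v] for g in graphs])
        for v in set_a | set_b
    }
    cross_edges = [
        e for e in edges if (set(e) & set_a) and (set(e) & set_b)
    ]
    edge_p = {e: np.mean([e in g for g in graphs]) for e in cross_edges}
    return node_p, edge_p, len(graphs)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values by the step-up definition, by hand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        q[i] = running
    return q
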