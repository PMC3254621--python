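"""Synthetic study generator: F2 intercross genotypes, epistatic phenotypes,
gene annotations, and protein-interaction networks.

The generator emulates the design of a two-strain (A/J x C57BL/6J style) F2
airway-responsiveness study: 115 F2 animals plus one "average" mouse per
parental strain, a genome-wide panel of 384 SNP markers over the 19 mouse
autosomes, and a phenotype in which only animals homozygous for the A-strain
allele at two unlinked loci show roughly doubled responsiveness. Meiosis uses
the Haldane map function (no crossover interference): the recombination
fraction between markers d cM apart is r = (1 - exp(-2d/100)) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cross import (
    AA,
    AB,
    BB,
    F2,
    MISSING,
    PARENTAL_A,
    PARENTAL_B,
    CrossData,
    GeneticMap,
    markers_dataframe,
)

#: Approximate physical lengths of the 19 mouse autosomes, Mb (GRCm38 scale).
MOUSE_AUTOSOME_MB = (
    195.5, 182.1, 160.0, 156.5, 151.8, 149.7, 145.4, 129.4, 124.6, 130.7,
    122.1, 120.1, 120.4, 124.9, 104.0, 98.2, 95.0, 90.7, 61.4,
)

#: Default map parameters emulating the study panel: 384 markers over 19
#: autosomes; 6.4 Mb spacing tiles the ~2.46 Gb of autosome with 384 markers;
#: 0.5 cM/Mb is the mouse genome-wide average recombination rate.
DEFAULT_N_AUTOSOMES = 19
DEFAULT_N_MARKERS = 384
DEFAULT_SPACING_MB = 6.4
DEFAULT_CM_PER_MB = 0.5

PHENOTYPE_FLOOR = 1e-6


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _allocate_markers(n_total: int, lengths: np.ndarray) -> np.ndarray:
    """Allocate markers to chromosomes proportionally to length, >=1 each.

    Each chromosome gets one marker up front; the remainder is distributed
    proportionally to length by largest remainder, so totals are exact.
    """
    k = len(lengths)
    if n_total < k:
        raise ParameterError("need at least one marker per autosome")
    extra = n_total - k
    quota = extra * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    short = extra - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base + 1


def make_map(
    n_autosomes: int = DEFAULT_N_AUTOSOMES,
    n_markers_total: int = DEFAULT_N_MARKERS,
    spacing_mb: float = DEFAULT_SPACING_MB,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    seed: int = 0,
) -> GeneticMap:
    """Build a uniformly spaced genome-wide SNP map.

    Markers are allocated to autosomes proportionally to (configured) mouse
    chromosome lengths and placed at multiples of ``spacing_mb`` from the
    chromosome start; genetic positions follow the fixed conversion
    pos_cM = pos_bp * cm_per_mb * 1e-6. ``seed`` is accepted for signature
    symmetry with the other generators; marker placement is deterministic.
    """
    if n_autosomes < 1 or n_markers_total < 1:
        raise ParameterError("n_autosomes and n_markers_total must be positive")
    if spacing_mb <= 0 or cm_per_mb <= 0:
        raise ParameterError("spacing_mb and cm_per_mb must be positive")
    if n_markers_total < n_autosomes:
        raise ParameterError("n_markers_total must be >= n_autosomes")
    lengths = np.array(
        [MOUSE_AUTOSOME_MB[i % len(MOUSE_AUTOSOME_MB)] for i in range(n_autosomes)],
        dtype=float,
    )
    counts = _allocate_markers(n_markers_total, lengths)
    rows = []
    chrom_lengths: dict[str, int] = {}
    for c in range(n_autosomes):
        chrom = str(c + 1)
        for i in range(counts[c]):
            pos_bp = int(round((i + 1) * spacing_mb * 1e6))
            pos_cm = pos_bp * cm_per_mb * 1e-6
            rows.append((f"m{chrom}_{i + 1:03d}", chrom, pos_cm, pos_bp))
        chrom_lengths[chrom] = int(round(lengths[c] * 1e6))
    return GeneticMap(markers_dataframe(rows), chrom_lengths_bp=chrom_lengths)


def _simulate_gametes(
    gmap: GeneticMap, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder-allele matrix (n_gametes x n_markers), 0 = A allele, 1 = B allele.

    Along each gamete the founder allele switches between adjacent markers
    with the Haldane recombination fraction of their cM distance;
    chromosomes segregate independently.
    """
    out = np.empty((n_gametes, gmap.n_markers), dtype=np.int8)
    for chrom in gmap.chromosomes:
        idx = gmap.marker_indices_on(chrom)
        m = len(idx)
        pos = gmap.table["pos_cm"].to_numpy()[idx]
        first = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
        if m > 1:
            r = haldane_r(np.diff(pos))
            switch = (rng.random((n_gametes, m - 1)) < r).astype(np.int8)
            parity = np.cumsum(switch, axis=1, dtype=np.int32) & 1
            alleles = np.concatenate(
                [first, first ^ parity.astype(np.int8)], axis=1
            )
        else:
            alleles = first
        out[:, idx] = alleles
    return out


def simulate_f2(gmap: GeneticMap, n_f2: int, seed: int = 0) -> CrossData:
    """Simulate F2 genotypes (phenotype unset).

    Each F2 genotype is the sum of two independent F1 gametes, so every
    marker segregates 1:2:1 (AA:AB:BB) and adjacent markers co-segregate
    according to the Haldane map function. Deterministic given ``seed``.
    """
    if n_f2 < 1:
        raise ParameterError("n_f2 must be >= 1")
    rng = np.random.default_rng(seed)
    gametes = _simulate_gametes(gmap, 2 * n_f2, rng)
    geno = (gametes[0::2] + gametes[1::2]).astype(np.int8)  # 0=AA,1=AB,2=BB
    ids = tuple(f"F2_{i + 1:03d}" for i in range(n_f2))
    return CrossData(gmap=gmap, genotypes=geno, mouse_ids=ids, origins=(F2,) * n_f2)


def add_parental_averages(cross: CrossData) -> CrossData:
    """Append one all-AA (strain A) and one all-BB (strain B) average row.

    These rows stand in for the parental strains, one "average" animal per
    strain, so the founders are represented without being over-weighted.
    """
    m = cross.gmap.n_markers
    geno = np.vstack(
        [cross.genotypes, np.full((1, m), AA, np.int8), np.full((1, m), BB, np.int8)]
    )
    ph = None
    if cross.phenotype is not None:
        raise ParameterError("add parental rows before simulating the phenotype")
    return CrossData(
        gmap=cross.gmap,
        genotypes=geno,
        mouse_ids=cross.mouse_ids + ("parentA_avg", "parentB_avg"),
        origins=cross.origins + (PARENTAL_A, PARENTAL_B),
        phenotype=ph,
    )


@dataclass(frozen=True)
class PhenoModel:
    """Epistatic phenotype model: only double-AA animals shift upward.

    mean_i = baseline_mean * effect_ratio^[g(locus_a)=AA and g(locus_b)=AA],
    plus Gaussian noise with sd ``noise_sd``, truncated below at a small
    positive floor. The two loci must lie on different chromosomes (the
    modelled interaction is inter-chromosomal).
    """

    locus_a: str
    locus_b: str
    baseline_mean: float = 1.0
    effect_ratio: float = 2.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be positive")
        if self.effect_ratio < 1:
            raise ParameterError("effect_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def simulate_phenotype(cross: CrossData, model: PhenoModel, seed: int = 0) -> CrossData:
    """Fill in the phenotype under an epistatic two-locus model.

    F2 animals receive the model mean plus Gaussian noise; parental-average
    rows receive their strain group mean exactly (the double-AA mean for the
    A-strain row, the baseline for the B-strain row), mirroring their role
    as strain averages.
    """
    gmap = cross.gmap
    for locus in (model.locus_a, model.locus_b):
        gmap.index_of(locus)
    if gmap.chrom_of(model.locus_a) == gmap.chrom_of(model.locus_b):
        raise ParameterError("model loci must lie on different chromosomes")
    rng = np.random.default_rng(seed)
    ga = cross.genotype_at(model.locus_a)
    gb = cross.genotype_at(model.locus_b)
    double_aa = (ga == AA) & (gb == AA)
    mean = model.baseline_mean * np.where(double_aa, model.effect_ratio, 1.0)
    ph = mean + rng.normal(0.0, model.noise_sd, size=cross.n_mice)
    orig = np.asarray(cross.origins)
    ph[orig == PARENTAL_A] = model.baseline_mean * model.effect_ratio
    ph[orig == PARENTAL_B] = model.baseline_mean
    ph = np.maximum(ph, PHENOTYPE_FLOOR)
    return cross.with_phenotype(ph)


def inject_missing_and_errors(
    cross: CrossData, missing_rate: float, error_rate: float, seed: int = 0
) -> CrossData:
    """Robustness fixture: drop genotype calls and flip others at random.

    Each F2 genotype cell is independently set to missing with probability
    ``missing_rate``, else flipped to a uniformly random other code with
    probability ``error_rate``. Parental-average rows are synthetic strain
    summaries and are left untouched.
    """
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    geno = cross.genotypes.copy()
    f2_rows = np.asarray(cross.origins) == F2
    g = geno[f2_rows]
    u_missing = rng.random(g.shape)
    u_error = rng.random(g.shape)
    shift = rng.integers(1, 3, size=g.shape)  # +1 or +2 mod 3: another code
    flipped = ((g + shift) % 3).astype(np.int8)
    g = np.where(u_error < error_rate, flipped, g)
    g = np.where(u_missing < missing_rate, np.int8(MISSING), g)
    geno[f2_rows] = g
    return CrossData(
        gmap=cross.gmap,
        genotypes=geno,
        mouse_ids=cross.mouse_ids,
        origins=cross.origins,
        phenotype=cross.phenotype,
    )


# ---------------------------------------------------------------------------
# gene annotation and gene->protein mapping
# ---------------------------------------------------------------------------

def make_gene_annotation(
    gmap: GeneticMap,
    genes_per_mb: float = 3.0,
    seed: int = 0,
    min_len_bp: int = 5_000,
    max_len_bp: int = 100_000,
) -> pd.DataFrame:
    """Random gene annotation over the map's chromosomes (1-based inclusive).

    Gene starts are uniform over each chromosome; counts scale with the
    chromosome length at ``genes_per_mb``. Returns columns
    gene_id, symbol, chromosome, start_bp, end_bp sorted by position.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for chrom, length in gmap.chrom_lengths_bp.items():
        n_genes = max(1, int(round(length / 1e6 * genes_per_mb)))
        starts = np.sort(rng.integers(1, max(2, length - max_len_bp), size=n_genes))
        lens = rng.integers(min_len_bp, max_len_bp + 1, size=n_genes)
        for s, ln in zip(starts, lens):
            gid += 1
            rows.append(
                (f"G{gid:05d}", f"Sym{gid:05d}", chrom, int(s), int(s + ln - 1))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chromosome", "start_bp", "end_bp"]
    )


def make_gene_protein_map(
    annotation: pd.DataFrame,
    unmapped_fraction: float = 0.1,
    seed: int = 0,
    always_mapped: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Gene -> protein identifier table; a fraction of genes stays unmapped.

    Emulates restriction to curated protein-coding entries (ESTs, predicted
    genes and non-coding RNAs have no protein product). Genes listed in
    ``always_mapped`` are never dropped.
    """
    rng = np.random.default_rng(seed)
    keep = rng.random(len(annotation)) >= unmapped_fraction
    keep |= annotation["gene_id"].isin(always_mapped).to_numpy()
    sub = annotation.loc[keep, ["gene_id"]].copy()
    sub["protein_id"] = "pr_" + sub["gene_id"]
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# protein-interaction network
# ---------------------------------------------------------------------------

STRING_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)


def _score_edge(rng: np.random.Generator) -> dict:
    """High-confidence non-literature evidence: combined > 800, experimental > 0."""
    attrs = {c: 0 for c in STRING_CHANNELS}
    attrs["experimental"] = int(rng.integers(400, 951))
    attrs["coexpression"] = int(rng.integers(0, 301))
    attrs["combined_score"] = int(rng.integers(801, 1001))
    return attrs


def simulate_ppin(
    n_nodes: int,
    n_edges: int,
    planted_edges: tuple[tuple[str, str], ...] = (),
    degree_skew: float = 0.0,
    seed: int = 0,
    node_ids: tuple[str, ...] | None = None,
) -> nx.Graph:
    """Simple undirected protein network with planted edges.

    Beyond the planted edges, edges are sampled with endpoint weights
    proportional to (degree + 1)^degree_skew; skew 0 gives a uniform
    G(n, m) background, larger skew a heavier-tailed degree distribution.
    Every edge carries STRING-style channel scores with combined_score > 800
    and positive experimental evidence, so the network survives the
    high-confidence filter. Planted node ids absent from the generated node
    set are added to it.
    """
    if n_nodes < 1:
        raise ParameterError("n_nodes must be positive")
    if degree_skew < 0:
        raise ParameterError("degree_skew must be non-negative")
    if node_ids is None:
        nodes = [f"p{i + 1:04d}" for i in range(n_nodes)]
    else:
        nodes = list(node_ids)
        if len(nodes) != len(set(nodes)):
            raise ParameterError("node_ids must be unique")
    for u, v in planted_edges:
        for w in (u, v):
            if w not in set(nodes):
                nodes.append(w)
        if u == v:
            raise ParameterError("planted edges must not be self-loops")
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ParameterError(f"n_edges {n_edges} exceeds simple-graph maximum {max_edges}")
    planted_idx = set()
    index = {v: i for i, v in enumerate(nodes)}
    for u, v in planted_edges:
        key = (min(index[u], index[v]), max(index[u], index[v]))
        if key in planted_idx:
            raise ParameterError("planted edges must be distinct")
        planted_idx.add(key)
    if len(planted_idx) > n_edges:
        raise ParameterError("more planted edges than n_edges")

    rng = np.random.default_rng(seed)
    edges = set(planted_idx)
    deg = np.zeros(n, dtype=float)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    if n_edges == max_edges:
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        stall = 0
        while len(edges) < n_edges:
            w = (deg + 1.0) ** degree_skew
            p = w / w.sum()
            batch = rng.choice(n, size=(max(64, n_edges - len(edges)), 2), p=p)
            added = False
            for a, b in batch:
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                if key in edges:
                    continue
                edges.add(key)
                deg[a] += 1
                deg[b] += 1
                added = True
                if degree_skew > 0 or len(edges) == n_edges:
                    break
            stall = 0 if added else stall + 1
            if stall > 50:  # dense regime: sample directly from absent pairs
                absent = [
                    (i, j)
                    for i in range(n)
                    for j in range(i + 1, n)
                    if (i, j) not in edges
                ]
                pick = rng.choice(len(absent), size=n_edges - len(edges), replace=False)
                for k in pick:
                    edges.add(absent[k])
                break

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b in sorted(edges):
        graph.add_edge(nodes[a], nodes[b], **_score_edge(rng))
    return graph


# ---------------------------------------------------------------------------
# the full synthetic study scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A complete synthetic study with known planted truth.

    ``planted_edges`` are the cross-locus protein interactions the
    prioritization stage should rank first; ``competing_edges`` are decoy
    cross-locus interactions whose endpoints are well connected elsewhere,
    so they are plausible under the degree-preserving null.
    """

    cross: CrossData
    model: PhenoModel
    annotation: pd.DataFrame
    gene2protein: pd.DataFrame
    ppin: nx.Graph
    planted_nodes_a: tuple[str, ...]
    planted_nodes_b: tuple[str, ...]
    planted_edges: tuple[tuple[str, str], ...]
    competing_edges: tuple[tuple[str, str], ...]


def _marker_near_fraction(gmap: GeneticMap, chrom: str, frac: float) -> str:
    idx = gmap.marker_indices_on(chrom)
    pos = gmap.table["pos_bp"].to_numpy()[idx]
    target = pos[0] + frac * (pos[-1] - pos[0])
    return gmap.table["marker"].iloc[idx[np.argmin(np.abs(pos - target))]]


def simulate_scenario(
    seed: int = 0,
    n_f2: int = 115,
    locus_chrom_a: str = "11",
    locus_chrom_b: str = "18",
    effect_ratio: float = 2.0,
    noise_sd: float = 0.3,
    genes_per_mb: float = 3.0,
    n_background_nodes: int = 280,
    n_background_edges: int = 900,
    ppin_window_mb: float = 12.0,
) -> Scenario:
    """Generate the default synthetic study: cross, annotation, mapping, PPIN.

    Two interacting loci are planted mid-chromosome on two different
    autosomes; genes within ~0.4 Mb of each peak marker host the planted
    cross-locus protein clique (2 proteins per locus, fully bipartite,
    no other interactions, so their joint connectivity is maximally
    surprising under a degree-preserving null). Four decoy cross-locus
    edges connect well-connected window proteins, and remaining window
    proteins attach only to the background network.
    """
    ss = np.random.SeedSequence(seed)
    s_cross, s_pheno, s_annot, s_map, s_ppin, s_misc = [
        int(x) for x in ss.generate_state(6) % (2**31)
    ]
    gmap = make_map()
    locus_a = _marker_near_fraction(gmap, locus_chrom_a, 0.5)
    locus_b = _marker_near_fraction(gmap, locus_chrom_b, 0.5)
    cross = add_parental_averages(simulate_f2(gmap, n_f2, seed=s_cross))
    model = PhenoModel(
        locus_a=locus_a, locus_b=locus_b, effect_ratio=effect_ratio, noise_sd=noise_sd
    )
    cross = simulate_phenotype(cross, model, seed=s_pheno)

    annotation = make_gene_annotation(gmap, genes_per_mb=genes_per_mb, seed=s_annot)
    rng = np.random.default_rng(s_misc)

    def window_genes(locus: str, half_mb: float) -> pd.DataFrame:
        chrom, pos = gmap.chrom_of(locus), gmap.pos_bp_of(locus)
        half = int(half_mb * 1e6)
        sub = annotation[
            (annotation["chromosome"] == chrom)
            & (annotation["end_bp"] >= pos - half)
            & (annotation["start_bp"] <= pos + half)
        ]
        return sub

    # guarantee genes tight around each peak to host the planted proteins
    extra_rows = []
    for tag, locus in (("a", locus_a), ("b", locus_b)):
        chrom, pos = gmap.chrom_of(locus), gmap.pos_bp_of(locus)
        for k in range(2):
            start = pos - 400_000 + k * 300_000
            extra_rows.append(
                (
                    f"Gplant_{tag}{k + 1}",
                    f"Plant{tag.upper()}{k + 1}",
                    chrom,
                    int(start),
                    int(start + 40_000),
                )
            )
    annotation = (
        pd.concat(
            [annotation, pd.DataFrame(extra_rows, columns=annotation.columns)],
            ignore_index=True,
        )
        .sort_values(["chromosome", "start_bp"], kind="stable")
        .drop_duplicates("gene_id")
        .reset_index(drop=True)
    )

    planted_genes = tuple(r[0] for r in extra_rows)
    gene2protein = make_gene_protein_map(
        annotation, unmapped_fraction=0.1, seed=s_map, always_mapped=planted_genes
    )
    g2p = dict(zip(gene2protein["gene_id"], gene2protein["protein_id"]))

    wa = window_genes(locus_a, ppin_window_mb)
    wb = window_genes(locus_b, ppin_window_mb)
    prots_a = [g2p[g] for g in wa["gene_id"] if g in g2p]
    prots_b = [g2p[g] for g in wb["gene_id"] if g in g2p]
    planted_a = tuple(g2p[g] for g in planted_genes[:2])
    planted_b = tuple(g2p[g] for g in planted_genes[2:])

    background = [f"bg{i + 1:04d}" for i in range(n_background_nodes)]
    ppin = simulate_ppin(
        n_nodes=n_background_nodes,
        n_edges=n_background_edges,
        degree_skew=1.0,
        seed=s_ppin,
        node_ids=tuple(background),
    )

    def attach(protein: str, k: int) -> None:
        targets = rng.choice(n_background_nodes, size=k, replace=False)
        for t in targets:
            if not ppin.has_edge(protein, background[t]):
                ppin.add_edge(protein, background[t], **_score_edge(rng))

    # planted bipartite clique; planted proteins have no other edges
    planted_edge_list: list[tuple[str, str]] = []
    for u in planted_a:
        for v in planted_b:
            ppin.add_edge(u, v, **_score_edge(rng))
            planted_edge_list.append((u, v))

    # decoy cross-locus edges between well-connected window proteins
    decoy_a = [p for p in prots_a if p not in planted_a]
    decoy_b = [p for p in prots_b if p not in planted_b]
    competing: list[tuple[str, str]] = []
    for k in range(min(4, len(decoy_a), len(decoy_b))):
        u, v = decoy_a[k], decoy_b[k]
        ppin.add_edge(u, v, **_score_edge(rng))
        attach(u, 8)
        attach(v, 8)
        competing.append((u, v))

    # remaining window proteins hang off the background only
    for p in decoy_a[len(competing):] + decoy_b[len(competing):]:
        attach(p, int(rng.integers(1, 4)))

    return Scenario(
        cross=cross,
        model=model,
        annotation=annotation,
        gene2protein=gene2protein,
        ppin=ppin,
        planted_nodes_a=planted_a,
        planted_nodes_b=planted_b,
        planted_edges=tuple(planted_edge_list),
        competing_edges=tuple(competing),
    )
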