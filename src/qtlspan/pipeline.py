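"""End-to-end pipeline: simulate/load -> scans -> thresholds -> windows ->
gene lists -> cross-locus prioritization, with a reproducible report.

Every stage draws its randomness from a seed derived as ``seed + stage
index``, so stages can be rerun in isolation; all artifacts embed the
config hash and seed, and a rerun with the same config produces
byte-identical outputs (logging goes to the logger, never into artifacts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .cross import AA, CrossData
from .network import (
    DEFAULT_MIN_COMBINED,
    DEFAULT_REQUIRED_CHANNELS,
    CandidateSets,
    cross_locus_subgraph,
    filter_string_edges,
    prioritize,
    tiered_graph,
)
from .scan import peak_pair, permutation_thresholds, scan_one, scan_two
from .simulate import simulate_scenario
from .windows import (
    extend_interval,
    genes_in_interval,
    nonrecombinant_span,
    select_high_responders,
)

log = logging.getLogger("qtlspan.pipeline")

_STAGES = (
    "simulate",
    "scan1",
    "scan2",
    "permtest",
    "peak",
    "windows",
    "genes",
    "prioritize",
    "report",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Flat pipeline configuration; unknown keys in a config file are errors."""

    # inputs: either a cross CSV (+ optional bp table) or simulation
    cross_csv: str | None = None
    marker_bp_tsv: str | None = None
    annotation_tsv: str | None = None
    gene2protein_tsv: str | None = None
    string_tsv: str | None = None
    # simulation parameters (used when cross_csv is None)
    n_f2: int = 115
    effect_ratio: float = 2.0
    noise_sd: float = 0.3
    # scan options
    n_perm: int = 200
    alpha: float = 0.05
    include_parental_averages: bool = True
    exclude_adjacent_cm: float = 0.0
    # window options
    flank_bp: int = 1_000_000
    window_sides: str = "both"
    # network options
    min_combined: int = DEFAULT_MIN_COMBINED
    channels: str = ",".join(DEFAULT_REQUIRED_CHANNELS)
    n_rand: int = 500
    swaps_per_edge: int = 10
    fdr_strong: float = 1e-4
    fdr_weak: float = 0.5
    # misc
    seed: int = 0
    out_dir: str = "qtlspan_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError("config", "config file must be a flat mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGES.index(stage)


def _load_or_simulate(config: PipelineConfig):
    if config.cross_csv is not None:
        for key in ("annotation_tsv", "gene2protein_tsv", "string_tsv"):
            if getattr(config, key) is None:
                raise PipelineError("simulate", f"{key} required when loading a cross")
        for key in ("cross_csv", "marker_bp_tsv", "annotation_tsv",
                    "gene2protein_tsv", "string_tsv"):
            p = getattr(config, key)
            if p is not None and not Path(p).exists():
                raise PipelineError("simulate", f"input file not found: {p}")
        bp = (
            qio.read_marker_bp(config.marker_bp_tsv)
            if config.marker_bp_tsv
            else None
        )
        cross = qio.read_cross_csv(config.cross_csv, bp_table=bp)
        annotation = qio.read_annotation_tsv(config.annotation_tsv)
        mapping = qio.read_gene_protein_map(config.gene2protein_tsv)
        string_records = qio.read_string_table(config.string_tsv)
        return cross, annotation, mapping, string_records, None
    scenario = simulate_scenario(
        seed=config.stage_seed("simulate"),
        n_f2=config.n_f2,
        effect_ratio=config.effect_ratio,
        noise_sd=config.noise_sd,
    )
    return (
        scenario.cross,
        scenario.annotation,
        scenario.gene2protein,
        None,
        scenario,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict and writes artifacts.

    A failure stops at the failing stage with prior artifacts intact and
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": int(config.seed)}
    report: dict = {"config": asdict(config), **meta, "stages": {}}

    # stage: simulate / load ------------------------------------------------
    try:
        cross, annotation, mapping, string_records, scenario = _load_or_simulate(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    log.info("simulate: %d mice x %d markers", cross.n_mice, cross.gmap.n_markers)
    qio.write_cross_csv(cross, out / "cross.csv")
    qio.write_marker_bp(cross.gmap, out / "markers_bp.tsv")
    qio.write_annotation_tsv(annotation, out / "annotation.tsv")
    qio.write_gene_protein_map(mapping, out / "gene2protein.tsv")
    if scenario is not None:
        qio.write_string_table(scenario.ppin, out / "string_links.txt")
        string_records = qio.read_string_table(out / "string_links.txt")
    scan_cross = (
        cross if config.include_parental_averages else cross.without_parental()
    )
    report["stages"]["simulate"] = {
        "n_mice": cross.n_mice,
        "n_mice_scanned": scan_cross.n_mice,
        "n_markers": cross.gmap.n_markers,
        "seed": config.stage_seed("simulate"),
        "simulated": scenario is not None,
    }

    # stage: scans ----------------------------------------------------------
    try:
        res1 = scan_one(scan_cross)
        qio.write_table(res1.table, out / "scan1.tsv")
        res2 = scan_two(scan_cross, exclude_adjacent_cm=config.exclude_adjacent_cm)
        qio.write_table(res2.table, out / "scan2.tsv")
    except Exception as exc:
        raise PipelineError("scan2", str(exc)) from exc
    report["stages"]["scan1"] = {
        "n_markers_scanned": len(res1.table),
        "max_lod": res1.max_lod(),
    }
    report["stages"]["scan2"] = {"n_pairs_scanned": len(res2.table)}

    # stage: permutation thresholds -----------------------------------------
    try:
        thr_int = permutation_thresholds(
            scan_cross,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.stage_seed("permtest"),
            statistic="max_int",
            exclude_adjacent_cm=config.exclude_adjacent_cm,
        )
        thr_1d = permutation_thresholds(
            scan_cross,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.stage_seed("permtest"),
            statistic="max_1d",
        )
    except Exception as exc:
        raise PipelineError("permtest", str(exc)) from exc
    qio.write_table(
        pd.DataFrame(
            {"max_int": thr_int.maxima, "max_1d": thr_1d.maxima}
        ),
        out / "perm_maxima.tsv",
    )
    report["stages"]["permtest"] = {
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "threshold_int": thr_int.threshold,
        "threshold_1d": thr_1d.threshold,
        "seed": config.stage_seed("permtest"),
    }

    # stage: peak pair -------------------------------------------------------
    ranked = peak_pair(res2, thr_int)
    if ranked.empty:
        raise PipelineError("peak", "two-locus scan produced no pairs")
    qio.write_table(ranked.head(50), out / "top_pairs.tsv")
    top = ranked.iloc[0]
    report["stages"]["peak"] = {
        "marker_a": top["marker_a"],
        "marker_b": top["marker_b"],
        "chrom_a": str(top["chrom_a"]),
        "chrom_b": str(top["chrom_b"]),
        "lod_int": float(top["lod_int"]),
        "significant": bool(top["significant"]),
    }

    # stage: windows ---------------------------------------------------------
    try:
        responders = select_high_responders(
            cross, top["marker_a"], top["marker_b"],
            include_parental=config.include_parental_averages,
        )
        intervals = {}
        for tag, marker in (("a", top["marker_a"]), ("b", top["marker_b"])):
            chrom = cross.gmap.chrom_of(marker)
            span = nonrecombinant_span(cross, responders, chrom, marker)
            intervals[tag] = extend_interval(
                cross.gmap, span, flank_bp=config.flank_bp, sides=config.window_sides
            )
    except Exception as exc:
        raise PipelineError("windows", str(exc)) from exc
    report["stages"]["windows"] = {
        "n_high_responders": int(len(responders)),
        **{
            f"interval_{tag}": {
                "chromosome": iv.chromosome,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "anchor_markers": list(iv.anchor_markers),
            }
            for tag, iv in intervals.items()
        },
    }

    # stage: gene lists ------------------------------------------------------
    gene_lists = {}
    for tag, iv in intervals.items():
        genes = genes_in_interval(annotation, iv)
        gene_lists[tag] = genes
        qio.write_table(genes, out / f"genes_{tag}.tsv")
    report["stages"]["genes"] = {
        f"n_genes_{tag}": int(len(g)) for tag, g in gene_lists.items()
    }

    # stage: prioritization --------------------------------------------------
    try:
        channels = tuple(c.strip() for c in config.channels.split(",") if c.strip())
        ppin = filter_string_edges(
            string_records, min_combined=config.min_combined, required_channels=channels
        )
        g2p = dict(zip(mapping["gene_id"], mapping["protein_id"]))
        sets_raw = {}
        n_unmapped = {}
        for tag, genes in gene_lists.items():
            ids = list(genes["gene_id"])
            mapped = [g2p[g] for g in ids if g in g2p]
            n_unmapped[tag] = len(ids) - len(mapped)
            sets_raw[tag] = mapped
        if n_unmapped["a"] or n_unmapped["b"]:
            log.warning(
                "unmapped genes dropped: %d (window a), %d (window b)",
                n_unmapped["a"], n_unmapped["b"],
            )
        sets = CandidateSets(sets_raw["a"], sets_raw["b"])
        cross_edges = cross_locus_subgraph(ppin, sets)
        result = prioritize(
            ppin,
            sets,
            fdr_strong=config.fdr_strong,
            fdr_weak=config.fdr_weak,
            n_rand=config.n_rand,
            swaps_per_edge=config.swaps_per_edge,
            seed=config.stage_seed("prioritize"),
        )
    except Exception as exc:
        raise PipelineError("prioritize", str(exc)) from exc
    qio.write_table(result.nodes, out / "priority_nodes.tsv")
    qio.write_table(result.edges, out / "priority_edges.tsv")
    display = tiered_graph(result, ppin)
    qio.write_sif(display, out / "cross_locus.sif")
    qio.write_graphml(display, out / "cross_locus.graphml")
    report["stages"]["prioritize"] = {
        "n_ppin_nodes": ppin.number_of_nodes(),
        "n_ppin_edges": ppin.number_of_edges(),
        "n_candidates_a": len(sets.set_a),
        "n_candidates_b": len(sets.set_b),
        "n_unmapped_a": n_unmapped["a"],
        "n_unmapped_b": n_unmapped["b"],
        "n_cross_edges": len(cross_edges),
        "n_strong_edges": len(result.strong_edges),
        "strong_edges": [list(e) for e in result.strong_edges],
        "n_rand": config.n_rand,
        "seed": config.stage_seed("prioritize"),
    }

    # stage: report ----------------------------------------------------------
    write_report(report, out)
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the machine-readable JSON and a human-readable text summary."""
    out = Path(out_dir)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    s = report["stages"]
    lines = [
        "qtlspan pipeline report",
        f"config hash: {report['config_hash']}  seed: {report['seed']}",
        "",
        f"mice: {s['simulate']['n_mice']} total, "
        f"{s['simulate']['n_mice_scanned']} scanned; "
        f"markers: {s['simulate']['n_markers']}",
        f"single-QTL scan: {s['scan1']['n_markers_scanned']} markers, "
        f"max lod {s['scan1']['max_lod']:.3f} "
        f"(5% threshold {s['permtest']['threshold_1d']:.3f})",
        f"two-QTL scan: {s['scan2']['n_pairs_scanned']} pairs, "
        f"{s['permtest']['n_perm']} permutations, "
        f"interaction threshold {s['permtest']['threshold_int']:.3f} "
        f"at alpha {s['permtest']['alpha']}",
        f"peak pair: {s['peak']['marker_a']} (chr {s['peak']['chrom_a']}) x "
        f"{s['peak']['marker_b']} (chr {s['peak']['chrom_b']}), "
        f"lod_int {s['peak']['lod_int']:.3f}, "
        f"significant: {s['peak']['significant']}",
        f"high responders (AA at both peaks): {s['windows']['n_high_responders']}",
    ]
    for tag in ("a", "b"):
        iv = s["windows"][f"interval_{tag}"]
        lines.append(
            f"window {tag}: chr {iv['chromosome']} "
            f"{iv['start_bp']:,}-{iv['end_bp']:,} bp "
            f"({iv['anchor_markers'][0]}..{iv['anchor_markers'][1]}), "
            f"{s['genes'][f'n_genes_{tag}']} genes"
        )
    p = s["prioritize"]
    lines += [
        f"PPIN after filter: {p['n_ppin_nodes']} proteins, "
        f"{p['n_ppin_edges']} interactions",
        f"candidates: {p['n_candidates_a']} (a) + {p['n_candidates_b']} (b); "
        f"unmapped dropped: {p['n_unmapped_a']} + {p['n_unmapped_b']}",
        f"cross-locus interactions: {p['n_cross_edges']}; "
        f"strong (node+edge FDR) subnetwork edges: {p['n_strong_edges']}",
    ]
    for u, v in p["strong_edges"]:
        lines.append(f"  strong: {u} -- {v}")
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
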