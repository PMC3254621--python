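"""Readers and writers for the pipeline's file formats.

* Cross CSV (rotated qtl-cross dialect): row 1 column headers (phenotype
  and metadata columns first, then marker ids), row 2 chromosomes, row 3
  cM positions (blank under non-marker columns), then one row per mouse
  with genotype codes AA/AB/BB and "-" for missing.
* Marker physical positions as TSV (marker_id, chromosome, pos_bp).
* Gene annotation as 1-based TSV or BED (0-based half-open, converted on
  read/write).
* Gene -> protein mapping TSV.
* Protein networks in the STRING detailed-links dialect (whitespace
  separated, header line, integer channel scores 0-1000), plus SIF and
  GraphML exports for Cytoscape.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cross import (
    F2,
    GENO_CODES,
    GENO_STRINGS,
    PARENTAL_A,
    PARENTAL_B,
    CrossData,
    GeneticMap,
    markers_dataframe,
)
from .network import STRING_CHANNELS
from .simulate import DEFAULT_CM_PER_MB
from .windows import ANNOTATION_COLUMNS, validate_annotation


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cross CSV
# ---------------------------------------------------------------------------

_META_COLUMNS = ("ar", "id", "origin")


def write_cross_csv(cross: CrossData, path: str | Path) -> None:
    """Rotated qtl-cross CSV: phenotype first, then id/origin, then markers."""
    gmap = cross.gmap
    markers = gmap.markers
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_META_COLUMNS) + markers)
        w.writerow(["", "", ""] + [str(c) for c in gmap.table["chrom"]])
        w.writerow(["", "", ""] + [repr(float(p)) for p in gmap.table["pos_cm"]])
        ph = cross.phenotype
        for i in range(cross.n_mice):
            codes = [GENO_STRINGS[int(c)] for c in cross.genotypes[i]]
            w.writerow(
                [
                    "" if ph is None else repr(float(ph[i])),
                    cross.mouse_ids[i],
                    cross.origins[i],
                ]
                + codes
            )


def write_marker_bp(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table[["marker", "chrom", "pos_bp"]].rename(
        columns={"marker": "marker_id", "chrom": "chromosome"}
    ).to_csv(path, sep="\t", index=False)


def read_marker_bp(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = {"marker_id", "chromosome", "pos_bp"} - set(t.columns)
    if missing:
        raise FormatError(f"marker bp table missing columns {sorted(missing)}")
    return t


def read_cross_csv(
    path: str | Path,
    bp_table: pd.DataFrame | None = None,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> CrossData:
    """Read the rotated cross CSV.

    Columns whose chromosome cell (row 2) is blank are metadata: ``ar`` is
    the phenotype, ``id``/``origin`` optional mouse metadata. Physical
    marker positions come from ``bp_table`` (see :func:`read_marker_bp`)
    when given, otherwise from the cM positions under the fixed
    ``cm_per_mb`` conversion.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError("cross CSV needs header, chrom, cM and data rows")
    header, chrom_row, cm_row = rows[0], rows[1], rows[2]
    is_marker = [bool(c.strip()) for c in chrom_row] + [True] * (
        len(header) - len(chrom_row)
    )
    marker_cols = [i for i, m in enumerate(is_marker[: len(header)]) if m]
    meta_cols = {header[i]: i for i in range(len(header)) if not is_marker[i]}
    if "ar" not in meta_cols:
        raise FormatError("cross CSV must have a phenotype column 'ar'")
    bp_lookup = None
    if bp_table is not None:
        bp_lookup = dict(zip(bp_table["marker_id"], bp_table["pos_bp"]))
    marker_rows = []
    for i in marker_cols:
        name = header[i]
        cm = float(cm_row[i])
        bp = (
            int(bp_lookup[name])
            if bp_lookup is not None and name in bp_lookup
            else int(round(cm / cm_per_mb * 1e6))
        )
        marker_rows.append((name, str(chrom_row[i]), cm, bp))
    gmap = GeneticMap(markers_dataframe(marker_rows))

    geno, ph, ids, orig = [], [], [], []
    for r, row in enumerate(rows[3:]):
        if not any(cell.strip() for cell in row):
            continue
        try:
            codes = [GENO_CODES[row[i].strip()] for i in marker_cols]
        except KeyError as exc:
            raise FormatError(f"bad genotype code {exc} in data row {r + 1}") from None
        geno.append(codes)
        ph.append(float(row[meta_cols["ar"]]) if row[meta_cols["ar"]].strip() else np.nan)
        ids.append(
            row[meta_cols["id"]] if "id" in meta_cols else f"mouse_{r + 1:03d}"
        )
        orig.append(row[meta_cols["origin"]] if "origin" in meta_cols else F2)
    phen = np.asarray(ph)
    return CrossData(
        gmap=gmap,
        genotypes=np.asarray(geno, dtype=np.int8),
        mouse_ids=tuple(ids),
        origins=tuple(orig),
        phenotype=None if np.isnan(phen).all() else phen,
    )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation)[list(ANNOTATION_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return validate_annotation(t)


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open): start = start_bp - 1, end = end_bp."""
    validate_annotation(annotation)
    with open(path, "w") as fh:
        for rec in annotation.itertuples(index=False):
            fh.write(
                f"{rec.chromosome}\t{rec.start_bp - 1}\t{rec.end_bp}\t"
                f"{rec.gene_id}\t0\t.\t{rec.symbol}\n"
            )


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    """Read BED back to 1-based inclusive coordinates; column 7 = symbol."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"BED line {ln}: need >= 4 fields")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            symbol = parts[6] if len(parts) >= 7 else name
            rows.append((name, symbol, chrom, start + 1, end))
    return validate_annotation(
        pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    )


def write_gene_protein_map(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping[["gene_id", "protein_id"]].to_csv(path, sep="\t", index=False)


def read_gene_protein_map(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "protein_id"} - set(t.columns)
    if missing:
        raise FormatError(f"gene->protein table missing columns {sorted(missing)}")
    return t


# ---------------------------------------------------------------------------
# STRING detailed links
# ---------------------------------------------------------------------------

_STRING_HEADER = ("protein1", "protein2") + STRING_CHANNELS + ("combined_score",)


def write_string_table(graph: nx.Graph, path: str | Path) -> None:
    """STRING detailed-links dialect (space separated, one record per edge)."""
    with open(path, "w") as fh:
        fh.write(" ".join(_STRING_HEADER) + "\n")
        for u, v, d in sorted(graph.edges(data=True)):
            scores = [str(int(d.get(c, 0))) for c in STRING_CHANNELS]
            fh.write(
                f"{u} {v} " + " ".join(scores) + f" {int(d.get('combined_score', 0))}\n"
            )


def read_string_table(path: str | Path) -> pd.DataFrame:
    """Parse detailed links; malformed records are skipped with one warning."""
    rows = []
    n_bad = 0
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[0] != "protein1":
            raise FormatError("not a STRING detailed-links file (bad header)")
        score_cols = header[2:]
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                n_bad += 1
                continue
            try:
                scores = [int(x) for x in parts[2:]]
            except ValueError:
                n_bad += 1
                continue
            if any(s < 0 or s > 1000 for s in scores):
                n_bad += 1
                continue
            rows.append(parts[:2] + scores)
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed STRING record(s)", stacklevel=2)
    return pd.DataFrame(rows, columns=["protein1", "protein2"] + score_cols)


# ---------------------------------------------------------------------------
# network exports and tabular results
# ---------------------------------------------------------------------------

def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
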