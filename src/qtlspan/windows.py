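"""Haplotype-window delimitation of linked loci and interval -> gene lists.

After a significant two-locus interaction is found, the animals that are
homozygous for the A-strain allele at both peak markers define the linked
haplotype: the locus is taken to extend over the maximal contiguous run of
markers at which none of those animals shows a crossover (i.e. all are AA;
a missing call cannot demonstrate a crossover and does not break the run).
The marker span is then extended by a physical flank (default 1 Mb, to
admit distal regulatory elements) and intersected with a gene annotation.

Coordinates are 1-based inclusive throughout this module; BED input/output
is converted at the file boundary (see :mod:`qtlspan.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import AA, MISSING, PARENTAL_A, PARENTAL_B, CrossData


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span (1-based, inclusive) anchored at two map markers."""

    chromosome: str
    start_bp: int
    end_bp: int
    anchor_markers: tuple[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise WindowError("start_bp must be <= end_bp")
        if self.start_bp < 1:
            raise WindowError("start_bp must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


ANNOTATION_COLUMNS = ("gene_id", "symbol", "chromosome", "start_bp", "end_bp")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise WindowError(f"annotation missing columns {sorted(missing)}")
    if (annotation["start_bp"] > annotation["end_bp"]).any():
        raise WindowError("annotation has records with start_bp > end_bp")
    if annotation["gene_id"].duplicated().any():
        raise WindowError("annotation gene_id values must be unique")
    return annotation


def select_high_responders(
    cross: CrossData,
    marker_a: str,
    marker_b: str,
    include_parental: bool = True,
) -> np.ndarray:
    """Indices of mice homozygous AA at both peak markers.

    These are the high-responder animals whose haplotypes delimit the
    non-recombinant span. The strain-A parental average row qualifies by
    construction and is included unless ``include_parental`` is False.
    """
    ga = cross.genotype_at(marker_a)
    gb = cross.genotype_at(marker_b)
    sel = (ga == AA) & (gb == AA)
    if not include_parental:
        orig = np.asarray(cross.origins)
        sel &= (orig != PARENTAL_A) & (orig != PARENTAL_B)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        warnings.warn(
            f"no mice are AA at both {marker_a} and {marker_b}", stacklevel=2
        )
    return idx


def nonrecombinant_span(
    cross: CrossData,
    mice: np.ndarray,
    chromosome: str,
    peak_marker: str,
) -> tuple[str, str]:
    """Maximal contiguous AA run around the peak marker in the selected mice.

    Returns (first_marker_id, last_marker_id) of the longest run of
    consecutive markers on ``chromosome`` containing ``peak_marker`` at
    which every selected mouse is AA or untyped: a crossover must be
    *observed* (an AB or BB call) to terminate the span.
    """
    mice = np.asarray(mice, dtype=int)
    if mice.size == 0:
        raise WindowError("mouse subset is empty")
    gmap = cross.gmap
    if gmap.chrom_of(peak_marker) != str(chromosome):
        raise WindowError(
            f"peak marker {peak_marker!r} is not on chromosome {chromosome!r}"
        )
    idx = gmap.marker_indices_on(chromosome)
    geno = cross.genotypes[np.ix_(mice, idx)]
    compatible = (geno == AA) | (geno == MISSING)
    all_ok = compatible.all(axis=0)
    peak_pos = int(np.flatnonzero(idx == gmap.index_of(peak_marker))[0])
    if not all_ok[peak_pos]:
        raise WindowError(
            f"subset contains an observed non-AA genotype at peak {peak_marker!r}; "
            "high-responder selection guarantees AA at the peak"
        )
    lo = peak_pos
    while lo > 0 and all_ok[lo - 1]:
        lo -= 1
    hi = peak_pos
    while hi < len(idx) - 1 and all_ok[hi + 1]:
        hi += 1
    markers = gmap.table["marker"].to_numpy()
    return str(markers[idx[lo]]), str(markers[idx[hi]])


def extend_interval(
    gmap,
    span: tuple[str, str],
    flank_bp: int = 1_000_000,
    chrom_length_bp: int | None = None,
    sides: str = "both",
) -> GenomicInterval:
    """Physical interval for a marker span, extended by ``flank_bp``.

    ``sides`` is ``"both"`` (default), ``"left"`` or ``"right"``; the result
    is clamped to [1, chrom_length_bp]. With flank 0 the interval is exactly
    the marker span.
    """
    if flank_bp < 0:
        raise WindowError("flank_bp must be non-negative")
    if sides not in ("both", "left", "right"):
        raise WindowError("sides must be 'both', 'left' or 'right'")
    first, last = span
    chrom = gmap.chrom_of(first)
    if gmap.chrom_of(last) != chrom:
        raise WindowError("span markers must lie on one chromosome")
    lo = gmap.pos_bp_of(first)
    hi = gmap.pos_bp_of(last)
    if lo > hi:
        raise WindowError("span markers must be ordered along the chromosome")
    if chrom_length_bp is None:
        chrom_length_bp = int(gmap.chrom_lengths_bp.get(chrom, hi))
    start = lo - (flank_bp if sides in ("both", "left") else 0)
    end = hi + (flank_bp if sides in ("both", "right") else 0)
    return GenomicInterval(
        chromosome=chrom,
        start_bp=max(1, start),
        end_bp=min(int(chrom_length_bp), end) if chrom_length_bp else end,
        anchor_markers=(first, last),
        provenance=f"span {first}..{last} +{flank_bp} bp ({sides})",
    )


def genes_in_interval(
    annotation: pd.DataFrame, interval: GenomicInterval
) -> pd.DataFrame:
    """Genes overlapping the interval by >= 1 bp.

    Any-overlap rule (not containment): a gene abutting either interval
    boundary by a single base is included. Deduplicated by gene_id, sorted
    by start position.
    """
    validate_annotation(annotation)
    on_chrom = annotation["chromosome"].astype(str) == str(interval.chromosome)
    if not on_chrom.any():
        warnings.warn(
            f"chromosome {interval.chromosome!r} absent from annotation",
            stacklevel=2,
        )
    sub = annotation[
        on_chrom
        & (annotation["start_bp"] <= interval.end_bp)
        & (annotation["end_bp"] >= interval.start_bp)
    ]
    return (
        sub.drop_duplicates("gene_id")
        .sort_values("start_bp", kind="stable")
        .reset_index(drop=True)
    )
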