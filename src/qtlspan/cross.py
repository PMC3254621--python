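"""Core containers for an F2 intercross: the genetic map and the cross data.

Genotypes are stored as a compact integer matrix (mice x markers) using the
codes in :data:`GENO_CODES`: 0 = AA (homozygous strain A), 1 = AB
(heterozygous), 2 = BB (homozygous strain B), -1 = missing. String codes
("AA"/"AB"/"BB"/"-") are used at the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA, AB, BB, MISSING = 0, 1, 2, -1

GENO_CODES = {"AA": AA, "AB": AB, "BB": BB, "-": MISSING}
GENO_STRINGS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "-"}

#: per-mouse origin tags
F2, PARENTAL_A, PARENTAL_B = "F2", "parental_A", "parental_B"


class MapError(ValueError):
    """Raised when a genetic map violates its ordering/uniqueness contract."""


class CrossError(ValueError):
    """Raised when cross data violate dimensional or coding contracts."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker panel: id, chromosome, position in cM and bp.

    Markers are ordered chromosome by chromosome; within a chromosome both
    cM and bp positions are strictly increasing. ``chrom_lengths_bp`` gives
    the assumed physical length of each chromosome (used to clamp interval
    extension); it defaults to the last marker position on each chromosome.
    """

    table: pd.DataFrame  # columns: marker, chrom, pos_cm, pos_bp
    chrom_lengths_bp: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos_cm", "pos_bp"}
        if not required.issubset(t.columns):
            raise MapError(f"map table must have columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise MapError(f"duplicate marker id {dup!r}")
        if (t["pos_bp"] <= 0).any():
            raise MapError("pos_bp must be positive")
        if (t["pos_cm"] < 0).any():
            raise MapError("pos_cm must be non-negative")
        for chrom, sub in t.groupby("chrom", sort=False):
            # genetically coincident markers (equal cM) are allowed; bp is strict
            if not (np.diff(sub["pos_cm"].to_numpy()) >= 0).all():
                raise MapError(f"pos_cm not non-decreasing on chrom {chrom}")
            if not (np.diff(sub["pos_bp"].to_numpy()) > 0).all():
                raise MapError(f"pos_bp not strictly increasing on chrom {chrom}")
        lengths = dict(self.chrom_lengths_bp)
        for chrom, sub in t.groupby("chrom", sort=False):
            last = int(sub["pos_bp"].max())
            lengths[str(chrom)] = max(int(lengths.get(str(chrom), 0)), last)
        object.__setattr__(self, "chrom_lengths_bp", lengths)
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(t["marker"])})

    # -- lookups ---------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["chrom"]:
            seen.setdefault(str(c), None)
        return list(seen)

    def index_of(self, marker: str) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise MapError(f"marker {marker!r} not in map") from None

    def chrom_of(self, marker: str) -> str:
        return str(self.table["chrom"].iloc[self.index_of(marker)])

    def pos_bp_of(self, marker: str) -> int:
        return int(self.table["pos_bp"].iloc[self.index_of(marker)])

    def pos_cm_of(self, marker: str) -> float:
        return float(self.table["pos_cm"].iloc[self.index_of(marker)])

    def marker_indices_on(self, chrom: str) -> np.ndarray:
        """Row indices (map order) of markers on one chromosome."""
        return np.flatnonzero((self.table["chrom"].astype(str) == str(chrom)).to_numpy())


def markers_dataframe(
    markers: Iterable[tuple[str, str, float, int]],
) -> pd.DataFrame:
    """Build a map table from (marker, chrom, pos_cm, pos_bp) tuples."""
    rows = list(markers)
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm", "pos_bp"])


@dataclass(frozen=True)
class CrossData:
    """An F2 intercross: genotype matrix, phenotype vector, mouse metadata.

    ``genotypes`` is int8, shape (n_mice, n_markers); ``phenotype`` is a
    float vector of airway responsiveness values (cm H2O*ml^-1*s per ug MCh
    per g body weight) or None when not yet simulated/measured. Rows tagged
    ``parental_A``/``parental_B`` are single "average" animals of the two
    founder strains and are all-AA / all-BB by construction.
    """

    gmap: GeneticMap
    genotypes: np.ndarray
    mouse_ids: tuple[str, ...]
    origins: tuple[str, ...]
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "mouse_ids", tuple(self.mouse_ids))
        object.__setattr__(self, "origins", tuple(self.origins))
        if g.ndim != 2 or g.shape[1] != self.gmap.n_markers:
            raise CrossError(
                f"genotype matrix shape {g.shape} does not match "
                f"{self.gmap.n_markers} markers"
            )
        n = g.shape[0]
        if len(self.mouse_ids) != n or len(self.origins) != n:
            raise CrossError("mouse_ids/origins length must equal mouse count")
        if len(set(self.mouse_ids)) != n:
            raise CrossError("mouse_ids must be unique")
        bad = set(np.unique(g)) - {AA, AB, BB, MISSING}
        if bad:
            raise CrossError(f"invalid genotype codes {sorted(bad)}")
        for tag in self.origins:
            if tag not in (F2, PARENTAL_A, PARENTAL_B):
                raise CrossError(f"invalid origin tag {tag!r}")
        orig = np.asarray(self.origins)
        if not (g[orig == PARENTAL_A] == AA).all():
            raise CrossError("parental_A rows must be AA at every marker")
        if not (g[orig == PARENTAL_B] == BB).all():
            raise CrossError("parental_B rows must be BB at every marker")
        if self.phenotype is not None:
            ph = np.asarray(self.phenotype, dtype=float)
            object.__setattr__(self, "phenotype", ph)
            if ph.shape != (n,):
                raise CrossError("phenotype length must equal mouse count")
            if not np.isfinite(ph).all() or (ph <= 0).any():
                raise CrossError("phenotype values must be finite and > 0")

    @property
    def n_mice(self) -> int:
        return self.genotypes.shape[0]

    def with_phenotype(self, phenotype: np.ndarray) -> "CrossData":
        return replace(self, phenotype=np.asarray(phenotype, dtype=float))

    def subset_mice(self, idx: Sequence[int] | np.ndarray) -> "CrossData":
        idx = np.asarray(idx, dtype=int)
        return CrossData(
            gmap=self.gmap,
            genotypes=self.genotypes[idx],
            mouse_ids=tuple(self.mouse_ids[i] for i in idx),
            origins=tuple(self.origins[i] for i in idx),
            phenotype=None if self.phenotype is None else self.phenotype[idx],
        )

    def without_parental(self) -> "CrossData":
        keep = [i for i, o in enumerate(self.origins) if o == F2]
        return self.subset_mice(keep)

    def genotype_at(self, marker: str) -> np.ndarray:
        return self.genotypes[:, self.gmap.index_of(marker)]

    def genotype_frame(self) -> pd.DataFrame:
        """Genotypes as a string-coded DataFrame (mice x markers)."""
        codes = np.vectorize(GENO_STRINGS.get)(self.genotypes)
        return pd.DataFrame(codes, index=list(self.mouse_ids), columns=self.gmap.markers)
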