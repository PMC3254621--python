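"""Single-QTL and two-dimensional two-QTL genome scans by marker regression.

The LOD score for a model X against the grand-mean null is
``lod = (n/2) * log10(RSS0 / RSS_X)`` computed on the complete cases of the
marker (or marker pair). The single-marker model fits one mean per observed
genotype class; the two-locus *full* model fits one mean per observed cell
of the 3x3 joint-genotype table, the *additive* model fits
mean + row effects + column effects (<= 5 free parameters), and the
interaction LOD is ``lod_int = lod_full - lod_add``. Genome-wide
significance is assessed by permuting the phenotype vector and recording
the per-permutation maximum statistic.

All pairwise quantities are obtained from genotype-indicator cross-products
(one matrix product per phenotype evaluation), and the additive-model
normal equations use per-pair Gram pseudoinverses precomputed once — the
genotype design is fixed under phenotype permutation — so a full 384-marker
two-QTL scan or one permutation costs a few hundred milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import CrossData

#: RSS values below REL_EPS * (scale of the data) are treated as exact fits,
#: reported as an infinite-LOD flag rather than an overflowing number.
REL_EPS = 1e-12


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanResult1D:
    """Per-marker single-QTL scan. ``table`` columns: marker, chrom, pos_cm,
    lod, n_used, infinite (RSS1 == 0), degenerate (< 2 observed classes)."""

    table: pd.DataFrame

    def lod_of(self, marker: str) -> float:
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise ScanError(f"marker {marker!r} not in scan result")
        return float(row["lod"].iloc[0])

    def max_lod(self) -> float:
        ok = ~(self.table["infinite"] | self.table["degenerate"])
        return float(self.table.loc[ok, "lod"].max()) if ok.any() else 0.0


@dataclass(frozen=True)
class ScanResult2D:
    """Per-pair two-QTL scan over unordered distinct marker pairs.

    ``table`` columns: marker_a, marker_b, chrom_a, pos_a_cm, chrom_b,
    pos_b_cm, lod_full, lod_add, lod_int, n_used, n_classes,
    infinite_full (full-model RSS == 0: lod_full and lod_int flagged),
    degenerate (< 2 observed joint classes: lods set to 0).
    """

    table: pd.DataFrame

    def pair_row(self, marker_a: str, marker_b: str) -> pd.Series:
        t = self.table
        hit = t[
            ((t["marker_a"] == marker_a) & (t["marker_b"] == marker_b))
            | ((t["marker_a"] == marker_b) & (t["marker_b"] == marker_a))
        ]
        if hit.empty:
            raise ScanError(f"pair ({marker_a}, {marker_b}) not in scan result")
        return hit.iloc[0]


@dataclass(frozen=True)
class PermThresholds:
    """Genome-wide permutation null of a maximum scan statistic.

    ``statistic`` is ``"max_1d"`` (maximum single-marker LOD), ``"max_int"``
    (pointwise maximum two-locus interaction LOD) or ``"max_int_condensed"``
    (chromosome-pair condensed M_full - M_add, the convention of classic
    two-locus scan software); ``maxima`` holds the
    per-permutation genome-wide maxima (infinite-flagged LODs excluded).
    Thresholds are empirical (1 - alpha) quantiles with linear (type-7)
    interpolation.
    """

    statistic: str
    maxima: np.ndarray
    alpha: float
    n_perm: int
    seed: int

    def threshold_at(self, alpha: float) -> float:
        if not 0.0 < alpha <= 1.0:
            raise ScanError("alpha must be in (0, 1]")
        return float(np.quantile(self.maxima, 1.0 - alpha))

    def empirical_pvalue(self, observed: float) -> float:
        """Exact Monte-Carlo p-value for an observed genome-wide maximum.

        Uses the (r + 1) / (N + 1) convention (the observed arrangement is
        itself one member of the permutation null), which keeps the test
        exact at finite permutation counts where a plug-in quantile
        threshold is slightly anti-conservative.
        """
        r = int((self.maxima >= observed).sum())
        return (r + 1) / (self.n_perm + 1)

    @property
    def threshold(self) -> float:
        return self.threshold_at(self.alpha)

    @property
    def threshold_1d(self) -> float | None:
        return self.threshold if self.statistic == "max_1d" else None

    @property
    def threshold_int(self) -> float | None:
        if self.statistic in ("max_int", "max_int_condensed"):
            return self.threshold
        return None


# ---------------------------------------------------------------------------
# single-marker scan
# ---------------------------------------------------------------------------

def _onehot(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3M) genotype indicator matrix and (n, M) typed mask."""
    n, m = genotypes.shape
    typed = genotypes >= 0
    z = np.zeros((n, 3 * m), dtype=float)
    rows, cols = np.nonzero(typed)
    z[rows, 3 * cols + genotypes[rows, cols]] = 1.0
    return z, typed


def _lod_from_rss(n: np.ndarray, rss0: np.ndarray, rss1: np.ndarray):
    """LOD and infinite-fit flag; both RSS clipped at 0 upstream."""
    scale = np.maximum(rss0, 1.0)
    infinite = (rss1 <= REL_EPS * scale) & (rss0 > REL_EPS * scale)
    null_flat = rss0 <= REL_EPS * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * (np.log10(rss0) - np.log10(rss1))
    lod = np.where(infinite | null_flat, 0.0, lod)
    lod = np.maximum(np.nan_to_num(lod, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    return lod, infinite


def scan_one(cross: CrossData) -> ScanResult1D:
    """Single-QTL genome scan: one genotype-class-means LOD per marker.

    Complete cases per marker; markers with fewer than two observed
    genotype classes get lod 0 and a ``degenerate`` flag (with a warning),
    perfect fits (residual sum of squares 0) an ``infinite`` flag.
    """
    y = _require_phenotype(cross)
    g = cross.genotypes
    z, typed = _onehot(g)
    m = g.shape[1]
    n3 = z.sum(axis=0).reshape(m, 3)
    s3 = (z * y[:, None]).sum(axis=0).reshape(m, 3)
    q3 = (z * (y**2)[:, None]).sum(axis=0).reshape(m, 3)
    n_used = n3.sum(axis=1)
    sum_y = s3.sum(axis=1)
    sum_y2 = q3.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = sum_y2 - np.where(n_used > 0, sum_y**2 / np.maximum(n_used, 1), 0.0)
        fit1 = np.where(n3 > 0, s3**2 / np.maximum(n3, 1), 0.0).sum(axis=1)
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(sum_y2 - fit1, 0.0)
    lod, infinite = _lod_from_rss(n_used, rss0, rss1)
    n_classes = (n3 > 0).sum(axis=1)
    degenerate = n_classes < 2
    lod = np.where(degenerate, 0.0, lod)
    infinite = np.where(degenerate, False, infinite)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} marker(s) with < 2 observed genotype "
            "classes: lod set to 0",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "marker": cross.gmap.markers,
            "chrom": cross.gmap.table["chrom"].astype(str).to_numpy(),
            "pos_cm": cross.gmap.table["pos_cm"].to_numpy(),
            "lod": lod,
            "n_used": n_used.astype(int),
            "infinite": infinite,
            "degenerate": degenerate,
        }
    )
    return ScanResult1D(table=table)


def _require_phenotype(cross: CrossData) -> np.ndarray:
    if cross.phenotype is None:
        raise ScanError("cross has no phenotype")
    y = cross.phenotype
    if np.unique(y).size < 2:
        raise ScanError("phenotype must take at least 2 distinct values")
    return y


# ---------------------------------------------------------------------------
# two-locus pair engine
# ---------------------------------------------------------------------------

class MarkerPairEngine:
    """Precomputed genotype-design state for fast two-locus evaluations.

    Holds, for every unordered marker pair, the joint-genotype cell counts,
    the complete-case count, and the pseudoinverse of the additive-model
    Gram matrix; :meth:`interaction_lod` and :meth:`all_lods` then need only
    cross-products with the (possibly permuted) phenotype. Pairs on the same
    chromosome closer than ``exclude_adjacent_cm`` are masked out
    (excluded); a value of 0 excludes nothing.
    """

    def __init__(self, cross: CrossData, exclude_adjacent_cm: float = 0.0):
        if cross.gmap.n_markers < 2:
            raise ScanError("need at least 2 markers for a two-locus scan")
        g = cross.genotypes
        self.gmap = cross.gmap
        self.m = g.shape[1]
        self.z, self.typed = _onehot(g)
        self.typed_f = self.typed.astype(float)
        m = self.m
        self.iu, self.ju = np.triu_indices(m, 1)
        # joint-genotype cell counts, viewed (M, 3, M, 3)
        n9 = self.z.T @ self.z
        self.t9 = n9.reshape(m, 3, m, 3)
        self.n_pair_mat = self.typed_f.T @ self.typed_f
        self.n_pair = self.n_pair_mat[self.iu, self.ju]
        self.n_classes = (self.t9 > 0).sum(axis=(1, 3))[self.iu, self.ju]

        chrom = cross.gmap.table["chrom"].astype(str).to_numpy()
        pos = cross.gmap.table["pos_cm"].to_numpy()
        self.chrom, self.pos_cm = chrom, pos
        same = chrom[self.iu] == chrom[self.ju]
        close = np.abs(pos[self.iu] - pos[self.ju]) < exclude_adjacent_cm
        self.excluded = same & close
        self.valid = (self.n_classes >= 2) & ~self.excluded

        # chromosome-pair group of each marker pair (for the condensed statistic)
        chrom_ids = {c: k for k, c in enumerate(cross.gmap.chromosomes)}
        cid = np.array([chrom_ids[c] for c in chrom])
        gid = cid[self.iu] * len(chrom_ids) + cid[self.ju]
        _, self.pair_group = np.unique(gid, return_inverse=True)
        self.n_groups = int(self.pair_group.max()) + 1 if len(gid) else 0

        self.gram_pinv = self._additive_gram_pinv()

    def _additive_gram_pinv(self) -> np.ndarray:
        iu, ju, t9 = self.iu, self.ju, self.t9
        p = len(iu)
        ca = t9.sum(axis=3)  # (M, 3, M): counts by class of marker a
        cb = t9.sum(axis=1)  # (M, M, 3): counts by class of marker b
        g = np.zeros((p, 5, 5))
        g[:, 0, 0] = self.n_pair
        a1, a2 = ca[iu, 1, ju], ca[iu, 2, ju]
        b1, b2 = cb[iu, ju, 1], cb[iu, ju, 2]
        g[:, 0, 1] = g[:, 1, 0] = a1
        g[:, 0, 2] = g[:, 2, 0] = a2
        g[:, 0, 3] = g[:, 3, 0] = b1
        g[:, 0, 4] = g[:, 4, 0] = b2
        g[:, 1, 1] = a1
        g[:, 2, 2] = a2
        g[:, 3, 3] = b1
        g[:, 4, 4] = b2
        g[:, 1, 3] = g[:, 3, 1] = t9[iu, 1, ju, 1]
        g[:, 1, 4] = g[:, 4, 1] = t9[iu, 1, ju, 2]
        g[:, 2, 3] = g[:, 3, 2] = t9[iu, 2, ju, 1]
        g[:, 2, 4] = g[:, 4, 2] = t9[iu, 2, ju, 2]
        return np.linalg.pinv(g, hermitian=True)

    def _pair_sums(self, y: np.ndarray):
        iu, ju, m = self.iu, self.ju, self.m
        yt = self.typed_f * y[:, None]
        y2t = self.typed_f * (y**2)[:, None]
        sum_y = (yt.T @ self.typed_f)[iu, ju]
        sum_y2 = (y2t.T @ self.typed_f)[iu, ju]
        s9 = ((self.z * y[:, None]).T @ self.z).reshape(m, 3, m, 3)
        return sum_y, sum_y2, s9

    def _rss_full_add(self, y: np.ndarray):
        iu, ju = self.iu, self.ju
        sum_y, sum_y2, s9 = self._pair_sums(y)
        with np.errstate(divide="ignore", invalid="ignore"):
            cell_fit = np.where(self.t9 > 0, s9**2 / np.maximum(self.t9, 1), 0.0)
        rss_full = np.maximum(sum_y2 - cell_fit.sum(axis=(1, 3))[iu, ju], 0.0)
        xty = np.empty((len(iu), 5))
        sa = s9.sum(axis=3)
        sb = s9.sum(axis=1)
        xty[:, 0] = sum_y
        xty[:, 1] = sa[iu, 1, ju]
        xty[:, 2] = sa[iu, 2, ju]
        xty[:, 3] = sb[iu, ju, 1]
        xty[:, 4] = sb[iu, ju, 2]
        beta = np.einsum("pij,pj->pi", self.gram_pinv, xty)
        rss_add = np.maximum(sum_y2 - np.einsum("pi,pi->p", beta, xty), rss_full)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss0 = sum_y2 - np.where(
                self.n_pair > 0, sum_y**2 / np.maximum(self.n_pair, 1), 0.0
            )
        return np.maximum(rss0, 0.0), rss_add, rss_full

    def all_lods(self, y: np.ndarray):
        """(lod_full, lod_add, lod_int, infinite_full) for every pair."""
        rss0, rss_add, rss_full = self._rss_full_add(y)
        lod_full, inf_full = _lod_from_rss(self.n_pair, rss0, rss_full)
        lod_add, _ = _lod_from_rss(self.n_pair, rss0, rss_add)
        lod_int, _ = _lod_from_rss(self.n_pair, rss_add, rss_full)
        zero = ~self.valid
        lod_full = np.where(zero, 0.0, lod_full)
        lod_add = np.where(zero, 0.0, lod_add)
        lod_int = np.where(zero, 0.0, lod_int)
        inf_full = np.where(zero, False, inf_full)
        return lod_full, lod_add, lod_int, inf_full

    def max_interaction_lod(self, y: np.ndarray) -> float:
        """Genome-wide maximum finite interaction LOD (permutation statistic)."""
        _, rss_add, rss_full = self._rss_full_add(y)
        lod_int, inf_flag = _lod_from_rss(self.n_pair, rss_add, rss_full)
        ok = self.valid & ~inf_flag
        return float(lod_int[ok].max()) if ok.any() else 0.0

    def max_interaction_lod_condensed(self, y: np.ndarray) -> float:
        """Chromosome-pair condensed interaction statistic.

        For each chromosome pair take M_full (maximum full LOD over the
        pair's marker grid) and M_add (maximum additive LOD, possibly at a
        different marker pair) and score the chromosome pair as
        M_full - M_add; return the maximum over chromosome pairs. This is
        how two-locus scan software conventionally summarizes interaction
        evidence in permutations, and it is bounded above by the pointwise
        maximum of lod_full - lod_add.
        """
        lod_full, lod_add, _, inf_full = self.all_lods(y)
        ok = self.valid & ~inf_full
        if not ok.any():
            return 0.0
        mf = np.full(self.n_groups, -np.inf)
        ma = np.full(self.n_groups, -np.inf)
        np.maximum.at(mf, self.pair_group[ok], lod_full[ok])
        np.maximum.at(ma, self.pair_group[ok], lod_add[ok])
        diff = mf - ma
        return float(diff[np.isfinite(diff)].max())


def scan_two(cross: CrossData, exclude_adjacent_cm: float = 0.0) -> ScanResult2D:
    """Two-dimensional two-QTL scan over all unordered marker pairs.

    Empty joint-genotype cells contribute no parameters (model degrees of
    freedom shrink with the observed cells); pairs with fewer than two
    observed joint classes are flagged ``degenerate`` with lods 0. Pairs on
    one chromosome closer than ``exclude_adjacent_cm`` are dropped from the
    result.
    """
    y = _require_phenotype(cross)
    eng = MarkerPairEngine(cross, exclude_adjacent_cm=exclude_adjacent_cm)
    lod_full, lod_add, lod_int, inf_full = eng.all_lods(y)
    markers = np.asarray(cross.gmap.markers)
    keep = ~eng.excluded
    table = pd.DataFrame(
        {
            "marker_a": markers[eng.iu][keep],
            "marker_b": markers[eng.ju][keep],
            "chrom_a": eng.chrom[eng.iu][keep],
            "pos_a_cm": eng.pos_cm[eng.iu][keep],
            "chrom_b": eng.chrom[eng.ju][keep],
            "pos_b_cm": eng.pos_cm[eng.ju][keep],
            "lod_full": lod_full[keep],
            "lod_add": lod_add[keep],
            "lod_int": lod_int[keep],
            "n_used": eng.n_pair[keep].astype(int),
            "n_classes": eng.n_classes[keep].astype(int),
            "infinite_full": inf_full[keep],
            "degenerate": (eng.n_classes < 2)[keep],
        }
    )
    return ScanResult2D(table=table)


def permutation_thresholds(
    cross: CrossData,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "max_int",
    exclude_adjacent_cm: float = 0.0,
) -> PermThresholds:
    """Genome-wide permutation null for the chosen maximum statistic.

    The phenotype vector is permuted uniformly among all mice (genotypes
    fixed); for each permutation the genome-wide maximum of the statistic is
    recorded, excluding infinite-flagged LODs. Deterministic given ``seed``.
    """
    if n_perm < 10:
        raise ScanError("n_perm must be >= 10")
    if not 0.0 < alpha <= 1.0:
        raise ScanError("alpha must be in (0, 1]")
    if statistic not in ("max_1d", "max_int", "max_int_condensed"):
        raise ScanError(
            "statistic must be 'max_1d', 'max_int' or 'max_int_condensed'"
        )
    y = _require_phenotype(cross)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    if statistic in ("max_int", "max_int_condensed"):
        eng = MarkerPairEngine(cross, exclude_adjacent_cm=exclude_adjacent_cm)
        stat = (
            eng.max_interaction_lod
            if statistic == "max_int"
            else eng.max_interaction_lod_condensed
        )
        for i in range(n_perm):
            maxima[i] = stat(rng.permutation(y))
    else:
        base = cross
        for i in range(n_perm):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = scan_one(base.with_phenotype(_positive(rng.permutation(y))))
            maxima[i] = res.max_lod()
    return PermThresholds(
        statistic=statistic, maxima=maxima, alpha=alpha, n_perm=n_perm, seed=seed
    )


def _positive(y: np.ndarray) -> np.ndarray:
    # CrossData requires positive phenotypes; permutation preserves values
    return y


def peak_pair(result: ScanResult2D, thresholds: PermThresholds | None = None) -> pd.DataFrame:
    """Rank marker pairs by interaction LOD (descending).

    Ties break lexicographically on (chrom_a, pos_a, chrom_b, pos_b);
    ``significant`` is set when a *finite* interaction LOD exceeds the
    genome-wide interaction threshold. Infinite-flagged pairs sort first but
    are never flagged significant (their interaction LOD is not a number).
    """
    t = result.table.copy()
    if t.empty:
        return t.assign(significant=pd.Series(dtype=bool))
    sort_key = np.where(t["infinite_full"], np.inf, t["lod_int"])
    t = t.assign(_key=sort_key)

    def chrom_key(c: pd.Series) -> pd.Series:
        return c.map(lambda x: (0, int(x)) if str(x).isdigit() else (1, str(x)))

    t = t.assign(_ca=chrom_key(t["chrom_a"]), _cb=chrom_key(t["chrom_b"]))
    t = t.sort_values(
        ["_key", "_ca", "pos_a_cm", "_cb", "pos_b_cm"],
        ascending=[False, True, True, True, True],
        kind="stable",
    ).drop(columns=["_key", "_ca", "_cb"])
    thr = thresholds.threshold_int if thresholds is not None else None
    if thr is None:
        sig = np.zeros(len(t), dtype=bool)
    else:
        sig = (~t["infinite_full"]) & (~t["degenerate"]) & (t["lod_int"] > thr)
    return t.assign(significant=sig).reset_index(drop=True)
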