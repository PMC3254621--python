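"""Haplotype-window delimitation: high-responder selection, non-recombinant
span (incl. the published worked example), interval extension and gene lists."""

import warnings

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_span, genes_overlapping
from qtlspan import (
    CrossData,
    GeneticMap,
    GenomicInterval,
    extend_interval,
    genes_in_interval,
    markers_dataframe,
    nonrecombinant_span,
    select_high_responders,
)
from qtlspan.cross import AA, AB, BB, F2, MISSING, PARENTAL_A
from qtlspan.windows import WindowError


def _table2_cross():
    """Six high-responder animals typed at the published chromosome-11
    markers (order as printed) plus the chromosome-18 peak marker.

    Only one animal is heterozygous at the proximal flanking marker and one
    is homozygous B at the distal flanking marker; positions are synthetic
    (the study's physical coordinates are not reproduced here).
    """
    rows = [
        ("rs13480836", "11", 25.0, 50_000_000),
        ("rs3659787", "11", 27.5, 55_000_000),
        ("rs13480853", "11", 30.0, 60_000_000),
        ("rs6398304", "11", 32.5, 65_000_000),
        ("rs6358426", "18", 20.0, 40_000_000),
    ]
    gmap = GeneticMap(markers_dataframe(rows))
    geno = np.full((6, 5), AA, dtype=np.int8)
    geno[2, 0] = AB  # mouse 3 heterozygous at rs13480836
    geno[4, 3] = BB  # mouse 5 homozygous B at rs6398304
    return CrossData(
        gmap=gmap,
        genotypes=geno,
        mouse_ids=tuple(f"mouse{i + 1}" for i in range(6)),
        origins=(F2,) * 6,
        phenotype=np.full(6, 2.0),
    )


class TestSelectHighResponders:
    def test_published_worked_example_selects_all_six(self):
        cross = _table2_cross()
        idx = select_high_responders(cross, "rs13480853", "rs6358426")
        assert len(idx) == 6

    def test_no_qualifying_mice_warns_and_returns_empty(self):
        cross = _table2_cross()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            idx = select_high_responders(cross, "rs6398304", "rs6358426")
        # mouse 5 is BB at rs6398304, the other five are AA: subset of 5
        assert len(idx) == 5 and not caught
        geno = cross.genotypes.copy()
        geno[:, 4] = BB
        cross2 = CrossData(
            gmap=cross.gmap, genotypes=geno, mouse_ids=cross.mouse_ids,
            origins=cross.origins, phenotype=cross.phenotype,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            idx = select_high_responders(cross2, "rs13480853", "rs6358426")
        assert len(idx) == 0 and len(caught) == 1

    def test_parental_a_row_always_selected(self):
        cross = _table2_cross()
        geno = np.vstack([cross.genotypes, np.full((1, 5), AA, np.int8)])
        cross2 = CrossData(
            gmap=cross.gmap, genotypes=geno,
            mouse_ids=cross.mouse_ids + ("pA",),
            origins=cross.origins + (PARENTAL_A,),
            phenotype=np.append(cross.phenotype, 2.0),
        )
        idx = select_high_responders(cross2, "rs13480853", "rs6358426")
        assert 6 in idx
        idx = select_high_responders(
            cross2, "rs13480853", "rs6358426", include_parental=False
        )
        assert 6 not in idx


class TestNonrecombinantSpan:
    def test_published_worked_example(self):
        # crossovers observed at rs13480836 (mouse 3) and rs6398304 (mouse 5)
        cross = _table2_cross()
        mice = select_high_responders(cross, "rs13480853", "rs6358426")
        span = nonrecombinant_span(cross, mice, "11", "rs13480853")
        assert span == ("rs3659787", "rs13480853")

    def test_no_crossover_spans_whole_chromosome(self):
        cross = _table2_cross()
        geno = np.full((6, 5), AA, dtype=np.int8)
        cross2 = CrossData(
            gmap=cross.gmap, genotypes=geno, mouse_ids=cross.mouse_ids,
            origins=cross.origins, phenotype=cross.phenotype,
        )
        span = nonrecombinant_span(cross2, np.arange(6), "11", "rs13480853")
        assert span == ("rs13480836", "rs6398304")

    def test_missing_genotype_does_not_break_the_run(self):
        cross = _table2_cross()
        geno = cross.genotypes.copy()
        geno[2, 0] = MISSING  # the observed crossover becomes an untyped call
        cross2 = CrossData(
            gmap=cross.gmap, genotypes=geno, mouse_ids=cross.mouse_ids,
            origins=cross.origins, phenotype=cross.phenotype,
        )
        mice = np.arange(6)
        span = nonrecombinant_span(cross2, mice, "11", "rs13480853")
        assert span == ("rs13480836", "rs13480853")

    def test_non_aa_peak_violates_contract(self):
        cross = _table2_cross()
        with pytest.raises(WindowError):
            nonrecombinant_span(cross, np.arange(6), "11", "rs6398304")

    def test_empty_subset_rejected(self):
        cross = _table2_cross()
        with pytest.raises(WindowError):
            nonrecombinant_span(cross, np.array([], dtype=int), "11", "rs13480853")

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_genotypes(self, seed):
        rng = np.random.default_rng(seed)
        n_markers = int(rng.integers(2, 7))
        n_mice = int(rng.integers(1, 5))
        rows = [
            (f"w{i}", "1", 5.0 * (i + 1), int(1e6 * (i + 1))) for i in range(n_markers)
        ]
        gmap = GeneticMap(markers_dataframe(rows))
        geno = rng.choice([AA, AB, BB, MISSING], size=(n_mice, n_markers)).astype(np.int8)
        peak = int(rng.integers(0, n_markers))
        geno[:, peak] = AA  # subset selection guarantees AA at the peak
        cross = CrossData(
            gmap=gmap, genotypes=geno,
            mouse_ids=tuple(f"m{i}" for i in range(n_mice)),
            origins=(F2,) * n_mice, phenotype=np.ones(n_mice),
        )
        got = nonrecombinant_span(cross, np.arange(n_mice), "1", f"w{peak}")
        lo, hi = brute_force_span((geno == AA) | (geno == MISSING), peak)
        assert got == (f"w{lo}", f"w{hi}")

    @pytest.mark.parametrize("seed", range(10))
    def test_widening_the_subset_never_widens_the_span(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_markers, n_mice = 6, 4
        rows = [(f"w{i}", "1", 5.0 * (i + 1), int(1e6 * (i + 1))) for i in range(n_markers)]
        gmap = GeneticMap(markers_dataframe(rows))
        geno = rng.choice([AA, AB, BB], size=(n_mice, n_markers), p=[0.7, 0.2, 0.1])
        geno = geno.astype(np.int8)
        geno[:, 2] = AA
        cross = CrossData(
            gmap=gmap, genotypes=geno,
            mouse_ids=tuple(f"m{i}" for i in range(n_mice)),
            origins=(F2,) * n_mice, phenotype=np.ones(n_mice),
        )
        small = nonrecombinant_span(cross, np.array([0, 1]), "1", "w2")
        big = nonrecombinant_span(cross, np.arange(n_mice), "1", "w2")
        order = {f"w{i}": i for i in range(n_markers)}
        assert order[big[0]] >= order[small[0]]
        assert order[big[1]] <= order[small[1]]


class TestExtendInterval:
    @pytest.fixture
    def gmap(self):
        rows = [
            ("s1", "3", 2.5, 5_000_000),
            ("s2", "3", 3.5, 7_000_000),
            ("s3", "3", 4.5, 9_000_000),
        ]
        return GeneticMap(
            markers_dataframe(rows), chrom_lengths_bp={"3": 100_000_000}
        )

    def test_flank_arithmetic(self, gmap):
        iv = extend_interval(gmap, ("s1", "s3"), flank_bp=1_000_000)
        assert (iv.start_bp, iv.end_bp) == (4_000_000, 10_000_000)
        assert iv.anchor_markers == ("s1", "s3")

    def test_start_clamped_to_one(self, gmap):
        rows = [("t1", "4", 0.25, 500_000), ("t2", "4", 0.5, 1_000_000)]
        gm = GeneticMap(markers_dataframe(rows))
        iv = extend_interval(gm, ("t1", "t2"), flank_bp=1_000_000)
        assert iv.start_bp == 1

    def test_end_clamped_to_chromosome_length(self, gmap):
        iv = extend_interval(gmap, ("s1", "s3"), flank_bp=95_000_000)
        assert iv.end_bp == 100_000_000

    def test_zero_flank_identity(self, gmap):
        iv = extend_interval(gmap, ("s1", "s3"), flank_bp=0)
        assert (iv.start_bp, iv.end_bp) == (5_000_000, 9_000_000)

    def test_monotone_in_flank(self, gmap):
        small = extend_interval(gmap, ("s1", "s3"), flank_bp=500_000)
        big = extend_interval(gmap, ("s1", "s3"), flank_bp=2_000_000)
        assert big.start_bp <= small.start_bp and big.end_bp >= small.end_bp

    def test_one_sided_modes(self, gmap):
        left = extend_interval(gmap, ("s1", "s3"), flank_bp=1_000_000, sides="left")
        right = extend_interval(gmap, ("s1", "s3"), flank_bp=1_000_000, sides="right")
        assert (left.start_bp, left.end_bp) == (4_000_000, 9_000_000)
        assert (right.start_bp, right.end_bp) == (5_000_000, 10_000_000)


class TestGenesInInterval:
    def _interval(self, start, end, chrom="5"):
        return GenomicInterval(
            chromosome=chrom, start_bp=start, end_bp=end, anchor_markers=("a", "b")
        )

    def _annotation(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "symbol", "chromosome", "start_bp", "end_bp"]
        )

    def test_empty_annotation(self):
        annot = self._annotation([])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert genes_in_interval(annot, self._interval(1, 100)).empty

    def test_abutting_gene_included(self):
        annot = self._annotation([("g1", "G1", "5", 1000, 2000)])
        hits = genes_in_interval(annot, self._interval(500, 1000))
        assert list(hits["gene_id"]) == ["g1"]
        none = genes_in_interval(annot, self._interval(500, 999))
        assert none.empty

    def test_absent_chromosome_warns(self):
        annot = self._annotation([("g1", "G1", "7", 1000, 2000)])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            hits = genes_in_interval(annot, self._interval(1, 10_000))
        assert hits.empty and len(caught) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(10):
            start = int(rng.integers(1, 50_000))
            rows.append(
                (f"g{k}", f"G{k}", rng.choice(["5", "6"]), start,
                 start + int(rng.integers(100, 5_000)))
            )
        annot = self._annotation(rows)
        iv = self._interval(10_000, 30_000)
        hits = genes_in_interval(annot, iv)
        assert set(hits["gene_id"]) == genes_overlapping(annot, "5", 10_000, 30_000)
        assert list(hits["start_bp"]) == sorted(hits["start_bp"])
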