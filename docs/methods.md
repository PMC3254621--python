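# Methods

This note documents the models behind `qtlspan`, the defaults and why they
were chosen, the numerical conventions, and the limits of what the
synthetic data can demonstrate.

## Study design emulated by the synthetic-data module

The generator reproduces the design of a two-strain mouse F2 intercross
study of native airway responsiveness (AR):

* **Animals.** 115 F2 animals plus exactly one "average" animal per
  parental strain — an all-AA row carrying the A-strain group mean and an
  all-BB row carrying the B-strain group mean — for 117 rows in every
  genetic analysis. The average rows represent the founders without
  over-weighting them; they are synthetic summaries, so missingness/error
  injection leaves them untouched.
* **Marker panel.** 384 SNP markers allocated to the 19 mouse autosomes
  proportionally to physical length and uniformly spaced at `spacing_mb`
  (default 6.4 Mb). 384 markers over the ~2.46 Gb of autosome imply ~6.4 Mb
  average spacing, so that default makes the panel genome-wide, as the
  study panel was; the spacing stays a parameter because quoted "average
  density" figures for such panels vary. The sex chromosomes are omitted
  (the emulated study used males only; hemizygosity modelling is out of
  scope). Genetic positions use a fixed 0.5 cM/Mb conversion, the mouse
  genome-wide average.
* **Meiosis.** Haldane's map function with no crossover interference:
  between markers $d$ cM apart, a gamete switches founder allele with
  probability $r = (1 - e^{-2d/100})/2$. Each F2 genotype is the sum of two
  independent F1 gametes, so every marker segregates 1:2:1 and chromosomes
  segregate independently. Haldane is the simplest standard choice; no
  claim about interference is intended.
* **Phenotype.** AR is modelled as
  `baseline_mean * effect_ratio^[AA at both loci] + N(0, noise_sd^2)`,
  truncated below at 1e-6 to preserve positivity. Defaults:
  `baseline_mean = 1` (AR in arbitrary units of
  cm H2O·ml⁻¹·s per µg MCh per g body weight), `effect_ratio = 2` (the
  "about double" responsiveness of double-homozygous-A animals), and
  `noise_sd = 0.3`. The noise default makes the nine genotype-group means
  separate cleanly at n = 117 (the double-AA group sits ~3 within-group SDs
  above the rest) while keeping the interaction evidence realistically
  marginal: typical planted interaction LODs land between ~7 and ~14
  against genome-wide 5% thresholds of ~6.5-7.5, the same regime as a real
  marginally-significant two-locus finding. The F2 phenotype is then
  approximately normal and unimodal, as such traits are reported to be.
* **Networks.** `simulate_ppin` builds a simple undirected graph with
  planted edges plus background edges sampled with endpoint weights
  `(degree + 1)^degree_skew` (skew 0 = uniform G(n, m)); every edge carries
  STRING-style channel scores with combined score > 800 and positive
  experimental evidence. The default scenario embeds a planted 2x2
  cross-locus clique whose proteins have no other interactions (their
  joint wiring is maximally surprising under a degree-preserving null),
  four decoy cross-locus edges between well-connected window proteins, and
  a preferential-attachment background.

**What the synthetic data do not emulate:** genotyping batch structure and
platform-specific error modes, crossover interference, linkage to the X
chromosome, dominance or multi-locus architectures beyond the single
planted epistatic pair, the true mouse gene density profile, and the true
modular topology of curated protein networks. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not performance guarantees on any particular real
dataset.

## Scans and LOD scores

Marker regression on typed markers only (complete cases per marker or per
pair); multipoint genotype-probability machinery is deliberately out of
scope because the emulated panel is essentially fully genotyped. For a
model $X$, $\mathrm{LOD}_X = \tfrac{n}{2}\log_{10}(\mathrm{RSS}_0 /
\mathrm{RSS}_X)$ with $\mathrm{RSS}_0$ from the grand mean of the same
complete cases. The single-marker model fits one mean per observed
genotype class. The two-locus full model fits one mean per *observed* cell
of the 3x3 joint table (empty cells contribute no parameters); the
additive model fits intercept + two genotype-class effects per locus
(<= 5 free parameters, fitted by minimum-norm least squares so collinear
or empty classes lose degrees of freedom gracefully);
`lod_int = lod_full - lod_add >= 0`.

Implementation: all pairwise statistics reduce to genotype-indicator
cross-products, and the additive-model Gram matrices depend only on
genotypes, so their pseudoinverses are precomputed once and reused across
phenotype permutations. A full 384-marker pair scan or one permutation
costs tens of milliseconds; results agree with explicit design-matrix
least squares to 1e-9 (tested).

Degenerate cases: a marker (pair) with fewer than two observed classes is
flagged and scored 0; an exact fit (RSS below 1e-12 of the data scale) is
carried as an explicit infinite-LOD flag rather than an overflowing
number, and flagged values are excluded from permutation maxima so they
cannot dominate thresholds.

## Permutation thresholds

The phenotype vector is permuted uniformly across all rows (genotypes
fixed, parental-average rows included, matching the emulated study's
117-row analysis); the genome-wide maximum of the chosen statistic is
recorded per permutation and the threshold is the empirical
$(1-\alpha)$ quantile with linear (type-7) interpolation — stated because
thresholds differ across quantile conventions. Three statistics are
available:

* `max_1d` — maximum single-marker LOD;
* `max_int` — pointwise maximum of `lod_int` over all marker pairs;
* `max_int_condensed` — for each chromosome pair, take the maximum full
  LOD and the maximum additive LOD over the pair's marker grid (possibly
  at different marker pairs) and score the chromosome pair as
  $M_f - M_a$; maximize over chromosome pairs. This is the summary
  convention of classic two-locus scan software, and it is bounded above
  by `max_int`. On a null cross of the study dimensions the 5% threshold
  is ~6.3-6.6 for the condensed statistic versus ~7.4-7.6 pointwise; the
  acceptance script reports the condensed one because that is the
  convention behind published two-locus interaction thresholds.

For calibration testing, `PermThresholds.empirical_pvalue` provides the
exact Monte-Carlo convention $p = (r+1)/(N+1)$ (the observed arrangement
counts as one permutation); at a few hundred permutations the plug-in
quantile threshold is a shade anti-conservative (realized level ~0.053 at
N = 200) while the exact convention keeps the test at level. The ranking
and reporting path (`peak_pair`, pipeline significance flags) uses the
quantile threshold; multiplicity across the pair grid is handled entirely
by the genome-wide max-statistic null — no per-pair FDR.

## Haplotype windows

Coordinates are 1-based inclusive internally; BED input/output is
converted at the file boundary (0-based half-open), because an off-by-one
here silently changes gene lists. A missing genotype inside a candidate
run counts as compatible — a crossover must be *observed* to delimit the
span. Interval extension defaults to 1 Mb on *both* ends (a one-sided mode
is exposed for users who prefer extending toward the telomere only), and
gene membership uses the any-overlap (>= 1 bp) rule, both chosen for
inclusiveness given the regulatory-element motivation for the flank.
Strand is ignored.

## Network prioritization

The null model is the configuration-model family sampled by double-edge
swaps: each randomization restarts from the observed network and performs
`swaps_per_edge * n_edges` (default 10x) attempted swaps, rejecting any
proposal that would create a self-loop or duplicate edge, which leaves the
uniform distribution over simple graphs with the observed degree sequence
invariant. Samples are drawn independently from per-sample seeds spawned
from one stream. On <= 6-node graphs the resulting node and edge p-values
match exhaustive enumeration of all degree-preserving simple graphs
(tested at 5,000 draws). Randomization is applied to the full filtered
network, not the bipartite subgraph, so null cross-locus counts reflect
genome-wide degree structure. Node and edge statistics share one set of
randomizations inside `prioritize`.

p-values use the $(r+1)/(N+1)$ pseudocount and are never exactly zero;
consequently the "strong" display tier (q < 1e-4, mirroring the
convention of reporting subnetworks whose nodes *and* edges both pass a
very stringent FDR) is only reachable with `n_rand` of order 1e4 or more.
Defaults: `min_combined = 800` (strict inequality), required channels
fusion/experimental/database (pure text-mining evidence is excluded),
BH adjustment per family (the FDR procedure itself is a design choice),
tiers strong (q < 1e-4) / weak (q < 0.5) / background. Gene-to-protein
mapping is a file input of opaque identifiers; unmapped genes are dropped
with a logged count.

## Pipeline

Stages run in order with seeds derived as `seed + stage_index`, so any
stage can be rerun in isolation; every artifact embeds the config hash and
seed, and a rerun with the same flat key-value config (unknown keys are
fail-fast errors) is byte-identical. Failure stops at the failing stage,
named in the raised error, with prior artifacts intact.

## Problem sizes used in the shipped checks

The test suite and acceptance script size their simulations to the study
scale where that is the point (117 x 384 null threshold at 200-500
permutations; planted-truth pipeline with 150 permutations and 400
randomizations) and to reduced panels where only calibration is at stake
(type-I error: 100 seeds x 200 permutations on a 40-marker, 4-autosome
panel of 60 animals; enumeration cross-checks on <= 6-node graphs at
5,000 randomizations). These sizes are the package's own trade-off between
Monte-Carlo resolution and a test suite that stays fast enough to run
habitually.

## Known limitations

* Marker regression only — no interval mapping between markers, no
  covariates, no non-normal phenotype models, no X chromosome, no
  multi-QTL model selection.
* The condensed interaction statistic reproduces the reporting convention
  of classic two-locus scans but, like that convention, mixes maxima taken
  at different grid points; the pointwise `max_int` statistic is the
  cleaner null for the pointwise peak ranking, and the pipeline uses the
  two consistently.
* Degree-preserving randomization conserves degrees exactly but nothing
  else (no edge-weight or annotation structure); evidence scores are not
  propagated to null networks.
* With few double-homozygous animals (a Binomial(115, 1/16) draw),
  two-locus localization is only a few markers wide and window widths vary
  a lot between runs — as they do in real marginal-power studies.
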