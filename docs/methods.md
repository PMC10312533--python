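# Methods

## Model and assumptions

`glycosim` treats a glycosite's quantification table as a nonnegative
glycopeptide × replicate matrix in which an exact 0 means *not observed*.
The method makes no distributional assumption about individual glycopeptide
abundances; all inference is resampling-based. Its core assumptions are:

1. Replicates within a group are exchangeable (no batch structure within a
   group). The internal-similarity quality checks exist precisely to test
   this assumption on the data at hand.
2. Missingness is informative (absence is a signal, not an NA to impute),
   which is why presence rates enter the similarity metric multiplicatively.
3. Groups are compared as collectives; per-glycopeptide conclusions are a
   ranking to guide follow-up, not hypothesis tests. No multiple-testing
   correction is applied, deliberately: the ranking is a guide, not a
   determinant.

## Standardization

Per replicate column: `L = log10(raw + 1)` (the +1 pseudocount keeps missing
values at exactly 0), then `A = L / ΣL` so each column's nonzero entries sum
to 1 ("relative log abundance"). Log-then-normalize was chosen over
normalize-then-log because the weighted Tanimoto behaves as intended on
bounded nonnegative values and per-replicate shares are comparable across
runs of different depth. With TIC scaling enabled, column r is multiplied by
`log10(TIC_r) / max_r log10(TIC_r)`; ratios are ≤ 1 so the weakest run is
shrunk, never inflated. A minimum-observation filter (default: 2 nonzero
observations across both groups combined; 0 disables) removes
single-observation identifications whose presence terms would be pure noise.

Group summaries average the standardized values over *observed* replicates
only: missingness is already penalized through the presence rate, and
including zeros in the mean would penalize it twice.

## The weighted similarity

For summaries A, B with presence rates P: per identification,
`K_i = 1 + (P_iA + P_iB)/2` (so 1 ≤ K ≤ 2), `d_i = |A_i − B_i|`, numerator
`A_iP_iA · B_iP_iB · K_i^(−d_i)`, and

`T = Σ num / (Σ(A P_A)² + Σ(B P_B)² − Σ num)`.

Since `num_i ≤ sqrt(denomA_i · denomB_i)`, T is always in [0, 1]; it is
symmetric, reduces to the classic Tanimoto when all presences are 1 and
distances 0, and is strictly decreasing in each `d_i`. K is per
identification because it is defined from that identification's mean
presence. Identifications absent from both sides contribute exactly 0 to all
three sums. A comparison whose denominator is 0 (both sides empty) is an
error, never similarity 1: it carries no information and would distort the
bootstrap distributions.

## Bootstrap collections

* Test collections: per group, 100 with-replacement draws of size n−1,
  deduplicated by replicate multiset (order ignored). 100 is a cap, not a
  guarantee: with n = 4 only C(6,3) = 20 distinct multisets exist.
* Null collections: datasets of size round-half-up((n_A+n_B)/2), drawing
  ⌈size/2⌉ from one group and ⌊size/2⌋ from the other with the odd member
  alternating sides (stratified, to keep sampling at an even rate from both
  groups). Two collections of 200 draws each are generated and deduplicated
  within and across collections; multisets drawn by both batches are
  assigned alternately to the two collections so that neither is starved
  when the distinct-multiset space is small (with 4+4 replicates only ~100
  distinct null datasets exist).
* Comparisons: Test = full cross product of the two test collections
  (≤ 10,000); Internal = unordered pairs within one test collection
  (≤ C(100,2) = 4,950); Null = cross product of the two null collections
  (≤ 40,000). All sampling flows through one seeded `numpy` Generator in a
  fixed order, so the entire analysis is a pure function of (inputs, seed).

## Densities and overlap

Distribution densities are Gaussian KDEs (Silverman bandwidth) evaluated on
a fixed 512-point grid over [0, 1] and renormalized to unit trapezoid
integral; a distribution with zero variance degrades to a Gaussian spike of
width 1e−3 at its value. The overlap of a Test density against a reference
density finds the crossing point x where the densities intersect, searched
*between* the two density means (KDE tails produce spurious crossings
elsewhere); among several crossings the one nearest the midpoint of the
means is used, and when no sign change exists between the means (nearly
coincident distributions) the midpoint itself is the split, which yields
α = β = 0.5 for identical densities. α is the reference mass on the Test
side of x, β the Test mass on the reference side. Both are computed from
unit-mass densities and are therefore invariant to density rescaling.

## Quality assessment

* **Internal Confidence.** `IC = |μ_Test − μ_Internal| / σ_Internal ·
  10^−(α+β)` with α, β from the Test-vs-Internal overlap; the absolute value
  follows the score's definition as an absolute distance between means.
  Pass requires IC ≥ 2 (≈ <5% chance the means coincide) *and* the Internal
  mean above the Test mean. An Internal mean within half the smaller SD of
  the Test mean is reported as `internal_equal_test` (a subset warning, no
  automatic action); below it, `internal_below_test` (the group is more
  variable against itself than against the other group and should not be
  treated as a unified group). σ uses the sample SD (ddof = 1).
* **Modality and outliers.** Peaks are local density maxima with prominence
  ≥ 5% of the maximum (a configurable choice; the grid is padded so edge
  maxima are detected), with comparisons assigned by the local-minimum
  boundaries between modes. For each (replicate, peak) the number of
  comparisons in the peak involving that replicate is z-scored against the
  other replicates' counts (the replicate under test is withheld from the
  mean/SD). A replicate is removable only when |z| > 3, the peak holds
  > 10% of comparisons, and it is under-represented in the primary peak or
  over-represented in a non-primary peak. The **primary peak** is the
  highest-similarity peak among those holding > 10% of comparisons (not the
  largest peak): a strong outlier replicate enters ~1 − (1 − 1/n)^(n−1) of
  resampled datasets, so contaminated comparisons can be the *majority* and
  the largest peak would be the outlier's own; a group's self-consistent
  mode is always the high-similarity mode of its internal distribution. The
  mass condition prevents a spurious low-mass density bump from claiming
  primacy. At most one replicate (largest |z|) is removed per group per
  round, removal is skipped when the group would drop below 3 replicates,
  and after removal the filter, bootstrap and distributions are rebuilt
  (max 2 rounds).
* **Typicality.** The Observed Similarity is typical when
  |obs − μ_Test| ≤ 3 σ_Test; strict mode instead requires it inside the
  empirical interquartile range of the Test values. Atypicality means the
  bootstrap does not faithfully simulate the comparison.
* A Null mean below the Test mean is reported as a warning only (it
  indicates extreme internal variability, which the Internal checks surface
  on their own).

## General comparison and ranking

The groups are differentiable when the Test-vs-Null overlap has α < 0.05 and
β < 0.20 (both configurable). Ranking uses *numerator-only* contributions:
the per-identification numerator term of each comparison, never divided by
the comparison denominator, because missing values bias the denominator most
in Null-type datasets and would mask exactly the identifications missingness
makes interesting. Each identification's score is the mean z of its Test
contributions in the context of its Null contributions
(`z_i = mean((c_test − μ_null,i) / σ_null,i)`); ranks ascend with z, and
drivers of differentiation ideally score below −2. A zero-variance Null
contribution yields a signed infinite sentinel (negative when the Test
contributes but the Null is constantly zero) and is flagged as degenerate
rather than silently ranked. Significant positive z indicates
interdependence between datasets rather than a driver.

Per-identification quality compares the id's Test contributions with its
Internal contributions in each group where the id was observed, using
32-bin histogram densities rather than KDE because contribution samples are
heavily zero-inflated; at that resolution α and β are not separable, so they
are combined: the id passes in a group when α + β ≥ 0.25, i.e. its Test
behavior overlaps its Internal behavior by at least 25%. Too little overlap
means the id behaves inconsistently between self- and cross-comparisons
(usually missingness-driven) and it is reported `LowQuality_File1/2/Both`;
an id never observed in a group's original matrix (resamples are not
consulted) is `UnseenIn_File1/2` instead.

## The synthetic-data generator

`glycosim.simulate` emulates a DDA quantification table at the scale of the
intended use case: a fixed panel of 20 glycoforms on one peptide backbone
with characteristic log10 abundances evenly spaced over 4.7–6.6 (a ~100-fold
dynamic range), lognormal replicate noise of 0.15 log10 units (≈ 40% CV),
4 replicates per group, and detection-limited missingness: the probability
of observing a value follows a logistic in its realized log10 abundance with
midpoint 4.3 and slope 25 — a deliberately sharp curve approximating an
instrument intensity cutoff, with the replicate noise supplying the
stochasticity around it. Under these defaults baseline presence is high and
missingness appears where it does in practice: when signal approaches the
detection limit.

Study conditions used by the calibration suites:

* **Null**: both groups drawn from the same generator (exchangeable).
* **Power**: the 3 lowest-abundance panel members suppressed 10-fold in
  group B, which pushes them below the detection limit — the
  absent-in-one-group regime that dominates real rankings. A 10-fold *gain*
  with presence intact moves the contribution z-statistic only through the
  AM-GM gap between A·B and ((A+B)/2)² on standardized shares (~1e−5) and
  cannot reach the z < −2 band; loss of presence is what the statistic is
  built to detect, so the power scenario injects exactly that.
* **Outlier**: 5 replicates per group with one replicate's raw abundances
  scaled by 0.1, which both shifts its standardized profile and knocks its
  low-abundance glycoforms below the detection limit.

Problem sizes throughout (20 ids, 4–5 replicates, 50 seeds per calibration
rate) are the package's own choice of desk-scale study conditions matching
the intended use case. What the generator does *not* model: chromatography
and charge-state artifacts, correlated glycoform biosynthesis, batch
effects, or abundance-independent (censoring-free) missingness. Tests
passing on these fixtures validate the statistical machinery, not
robustness to every artifact of real LC-MS data. With only 4 replicates the
outlier screen also has a real false-positive rate on clean data
(occasionally removing a legitimate replicate); this mirrors the method's
sensitivity at n = 4 and is why removal is capped at one replicate per
round and disabled below 4 replicates.

## Numerical and degenerate-input choices

* Blank/NA cells ingest as 0; duplicate identification rows are summed (to
  tolerate charge-state-merged exports) with a logged warning; negative
  values are an error.
* Identifier tokens without a composition block parse as peptide-only ids
  with zero composition and a warning; malformed brace blocks are errors.
* Round-half-up for the null dataset size; dataset identity is the sorted
  multiset of (group, replicate) members.
* Comparisons with empty denominators are dropped from distributions with a
  logged count; a distribution in which every pair was empty is an error.
* Ranking ties in z break deterministically on the canonical identifier;
  CSV outputs use fixed float formats so identical inputs and seed produce
  byte-identical files.
* `rescale_b` applies a user-supplied multiplicative factor to group B's raw
  abundances before standardization (for externally determined scale
  shifts); fitting such a factor is out of scope.

## Known limitations

* Per-id contribution overlap at 32 bins is coarse by construction; the
  0.25 combined threshold should be read as a consistency screen, not a
  calibrated test.
* Subgroup discovery is out of scope: persistent multimodality after
  outlier removal is reported but not resolved into subgroups.
* The tool assesses differentiability and ranks candidates; it does not
  produce p-values, and its output should feed targeted follow-up rather
  than stand as a final determination.
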