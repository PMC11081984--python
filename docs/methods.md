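# Methods

This note documents the models, parameters and numerical choices behind
`lcqspatial`, in the spirit of a statistical methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The local colocation quotient

For a marked planar point pattern with `N_A` cells of which `N_B` carry the
positive mark, the per-cell statistic is

    LCQ(i) = ( n_B(i) / n_A(i) ) / ( (N_B − 1) / (N_A − 1) ),

with kernel-weighted local counts over all other cells j ≠ i

    n_A(i) = Σ_j w_ij,   n_B(i) = Σ_{j positive} w_ij,
    w_ij = exp( −d_ij² / (2 h_i²) ).

Choices and their reasons:

* **Unnormalised Gaussian kernel.**  Any kernel normalisation constant
  cancels in the ratio `n_B/n_A`, so none is applied.
* **Adaptive bandwidth** `h_i` = Euclidean distance from cell *i* to its
  k-th nearest other cell, k = 10 by default (configurable).  Density-adaptive
  bandwidths keep the "local area" comparable between dense epithelium and
  sparse stroma.  Ties are resolved by the k-th order statistic of the sorted
  distance multiset.  Duplicate coordinates that drive `h_i` to zero are an
  error.
* **Asymmetric weighting.**  `w_ij` uses the focal cell's bandwidth only; no
  symmetrisation between pairs.
* **Uniform denominator.**  The global ratio `(N_B−1)/(N_A−1)` is applied at
  every focal cell regardless of its own label, and the quotient is evaluated
  at all cells (positive and negative).  The classical colocation quotient
  literature sometimes uses a different denominator at non-target focal
  cells; the uniform form is used here deliberately and consistently, and
  all oracles in the test suite encode it.
* **Truncation.**  Kernel evaluation is truncated beyond `r·h_i`
  (default r = 4) for the KD-tree accelerated path.  Each omitted pair has
  weight < exp(−r²/2), so the absolute error in `n_A(i)` is below
  `(N_A−1)·exp(−r²/2)` and the relative error is at most
  `(N_A−1)·exp(−r²/2)/n_A(i)`; at r = 4 the per-pair cap is exp(−8) ≈ 3.4e−4.
  Passing `truncation_radius=None` evaluates every pair exactly (blocked
  dense evaluation).  A test verifies the measured truncation error against
  the analytic bound.
* **Edge effects.**  No boundary correction is applied; quotients within
  ~one bandwidth of the domain edge are biased toward their interior
  neighbourhood.  This is a documented, deliberate omission.

### Significance

The null is **random labelling**: the `N_B` positive labels are
redistributed uniformly at random over the fixed cell positions, preserving
geometry, bandwidths and `N_B`.  Since only `n_B(i)` varies between
permutations, the implementation precomputes the sparse weight matrix once
and evaluates all permutations as one matrix product.  Per cell,

    p_raw(i) = (1 + #{ permutations with LCQ_perm(i) ≥ LCQ_obs(i) }) / (n_perm + 1),

the add-one conditional Monte-Carlo estimator with the conservative `≥` tie
convention (equality on the natural scale is compared on the weighted counts
`n_B`, which share every floating-point operation with the observed value,
so degenerate label sets tie exactly).  `p_raw` is corrected across cells by
Benjamini–Hochberg; a hotspot call requires `q_fdr ≤ α` (default 0.05)
**and** `LCQ_obs > 1`.  An explicit permutation seed is mandatory.  Note
that with `n_perm` permutations the smallest attainable `p_raw` is
`1/(n_perm+1)`; with many cells under FDR correction, `n_perm = 999` is a
practical minimum for usable q-values (199 permutations cannot produce
q ≤ 0.05 on patterns with thousands of cells).

## 2. Synthetic tissue generator

The generator emulates the data structure the analyses assume, not histology
imagery.  One simulated "gland" is a field (default 5000 × 5000 µm, image
convention: origin top-left, y downward) containing:

* **Lobules** — `n_lobules` = 30 disc territories of radius 260 µm placed by
  rejection sampling with hard non-overlap (placement failure after a
  bounded number of attempts is a config error naming the first unplaceable
  lobule).
* **Alveoli** — 10 per lobule, each an elliptical lumen (base radius
  N(25, 6) µm truncated to ±2.5 sd and ≥ 6 µm; axis ratio U(0.6, 1); random
  orientation) surrounded by a ring of 20 luminal epithelial cells at
  jittered equal angles on an 8 µm annulus starting 2 µm outside the lumen
  boundary.  The 2 µm clearance keeps rasterised cells off void pixels at
  the default 2 µm/px mask resolution.
* **Labels** — hierarchical: each lobule is latently "committed" with
  probability `commitment_fraction` = 0.4; given the lobule state each
  alveolus commits with probability 0.9 (committed lobule) or 0.05
  (uncommitted); given the alveolus state each epithelial cell is positive
  with probability `p_cell_high` = 0.9 or `p_cell_low` = 0.05.  This
  produces the bimodal grade distribution (alveoli are mostly grade 1 or
  grade 4) and the within-lobule correlation that the neighbour analysis
  detects.
* **Shed cells** — Poisson(0.2) per lumen, placed ≥ 2 µm inside the lumen
  boundary, labelled with the parent alveolus' cell probability.
* **Stroma** — Poisson background at 150 cells/mm², kept 2 µm clear of all
  lumina, positive with probability 0.02 (marker expression is not
  restricted to luminal epithelium).
* **Dimensions are label-blind** by construction, so any
  dimension-vs-positivity comparison is a calibrated null.

Counts (lobules per field, alveoli per lobule, ring cells per alveolus) are
**fixed at the rounded configured means** rather than drawn from Poisson
distributions.  This is a deliberate design choice: it makes the exact
binomial mixture the closed-form oracle for the grade distribution and
keeps "a 12-cell alveolus" exactly 12 cells.  Variability enters through
geometry, labels, shed cells and stroma.

The default parameter set is the package's fixed "study conditions": a
300-alveolus gland mirrors the scale of a graded slide (the study graded
25 alveoli per slide from slides holding hundreds), 20-cell rings are a
plausible section-plane count for an alveolar ring, and the commitment
probabilities were chosen once to produce strong grade-1/grade-4 bimodality
with `p_cell_high/low` = 0.9/0.05.

**Determinism.**  One `numpy` Generator seeded from `SimConfig.seed` drives
every draw in a fixed order (lobule centres → per lobule: state, alveolus
geometry/placement → per alveolus: commitment, ring angles, radial offsets,
labels, shed cells → stroma → mask fix-ups).  Identical configs give
byte-identical outputs; all coordinates are rounded to 1 nm (3 decimals in
µm) so serialisation is lossless.

**Void mask.**  A pixel is void when its centre lies inside a lumen ellipse
(single-channel PNG, 0 = tissue, 255 = void).  Because pixelation can
disagree with the continuous margins by up to half a pixel diagonal, a
deterministic fix-up pass nudges the rare offending cell: epithelial cells
step radially outward, shed cells shrink toward the lumen centre, stromal
cells resample.  The invariants (no epithelial/stromal cell on a void pixel,
every shed cell on one) then hold exactly and are tested.

**Adjacency.**  Two alveoli are adjacent when they share a lobule and their
lumen centres lie within `adjacency_factor` = 2.5 × the mean nearest-centre
spacing of that lobule.  "Immediately adjacent" has no canonical definition
on tissue; this rule gives a mean degree ≈ 5–6 at the default packing,
consistent with rings of abutting neighbours.

## 3. Alveolus-level analyses

* **Grading.**  Grade = 1/2/3/4 for positive fractions in [0, 0.25],
  (0.25, 0.5], (0.5, 0.75], (0.75, 1].  The half-open-above convention keeps
  the printed anchor percentages (25/50/75) in the lower grade and assigns
  every fraction exactly one grade.  Only luminal epithelial cells count.
  An alveolus is "positive" when it has ≥ 1 positive luminal epithelial
  cell (any degree of positivity).
* **Sampling.**  Seed alveoli are drawn without replacement, stratified by
  positivity, under an explicit seed (default 25 per stratum per gland).
* **Neighbour analysis.**  For each seed, the percentage of its adjacent
  same-lobule alveoli that are positive.  Isolated alveoli are dropped with
  a logged count, not an error.  Strata are compared by a two-sided
  Mann–Whitney test; per-seed percentages are pooled across glands before
  testing, mirroring the study's pooling across quarters and animals.
* **Rank test.**  Mid-rank tie handling throughout.  When the number of
  group assignments C(n1+n2, n1) ≤ 20 000 the two-sided p-value is computed
  by exact enumeration (deviation of U from its mean); otherwise the normal
  approximation with tie and continuity corrections is used.  Completely
  tied inputs give p = 1 by convention.  Groups below 3 observations are an
  error.
* **Dimension comparison.**  The same rank test applied to lumen major and
  minor semi-axes between positivity strata.

## 4. What passing tests do and do not show

The generator is a model of the *statistical* structure of stained
sections: binary labels on exact centroids, elliptical lumina, exchangeable
cells within an alveolus.  It does not model segmentation error, staining
intensity gradients, section-plane effects, duct systems, or multi-marker
panels — so passing tests demonstrate that the statistics recover planted
structure of the assumed form, not that they are robust to those real-data
artefacts.

Known statistical limitations, deliberately mirrored from the study design
and verified empirically in the suite:

* Pooling seed percentages across glands ignores gland- and lobule-level
  clustering.  Because seeds within a lobule share neighbours, the pooled
  Mann–Whitney null is mildly anti-conservative (≈13% rejection at α = 0.05
  in a one-gland shuffled-label experiment); with one seed per lobule the
  test is nominal.  The planted neighbour effect is orders of magnitude
  larger than this inflation.
* The permutation test conditions on the observed geometry; its per-cell
  p-values are strongly correlated between cells with overlapping kernels,
  so the *fraction* of sub-threshold cells in one pattern has far higher
  variance than a binomial count.  The marginal per-cell rate is exactly
  `⌊0.05(n_perm+1)⌋/(n_perm+1)` under the null, which the calibration test
  verifies across replicates.
* No edge correction (see §1).

## 5. Problem sizes in the suite

The test suite and acceptance script run at the sizes the analyses are
designed for: full 300-alveolus glands (~10 000 cells) for the grading,
neighbour and pipeline checks; 500-cell patterns × 999 permutations × 50
replicates for permutation calibration; 30 patterns up to 1 000 cells for
the numerical-equivalence oracle; 100 scaled-down glands (8 lobules) for
the dimension-null calibration.  These sizes were chosen so each property
is measured with useful statistical power while the whole suite stays quick
to run on one core.
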