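# Methods

## The rank-one model

A specimen's setation is an *m* × 20 matrix **A** of nonnegative counts,
one row per trunk limb (numbered from 2, the first limb behind the
maxilliped), one column per homologous setal group. The model assumes the
expected count factorizes, a_ij ≈ c·x_i·y_j: a limb effect, a group
effect, no interaction. The fitted (c, x, y) minimize the squared
Frobenius residual Σ (a_ij − c·x_i·y_j)²; with x and y constrained to unit
sum-of-squares this optimum is the leading singular triple of **A**.
Signs are fixed by flipping (x, y) jointly so Σx > 0, which for a
nonnegative matrix makes both vectors nonnegative. The scale c then
carries all the magnitude and behaves as an age proxy: it grows with the
overall setation of the animal.

Three solvers are exposed:

- `svd` (default): dense `numpy.linalg.svd`, exact to machine precision.
- `power`: power iteration on AᵀA, deterministic start at the column-sum
  direction, relative tolerance 1e-12, at most 10 000 iterations. Kept as
  an independent cross-check of the dense route; the two must agree to
  1e-8.
- `als_masked`: alternating least squares over the unmasked entries only,
  warm-started from the dense triple of the zero-filled grid, stopping
  when the residual decreases by less than 1e-10 (relative), at most
  1 000 sweeps. This is the solver for grids where missing segments are
  excluded rather than zero-filled; with an all-true mask it reproduces
  the SVD answer to 1e-6.

An all-zero (or all-masked) grid raises a degenerate-input error: c is
undefined.

### Missing data

Posterior limbs of young specimens lack whole ramal segments; the
corresponding cells are recorded as missing, not zero. Two policies are
provided. The default, `zero`, fills missing cells with 0 before fitting,
on the reasoning that a segment which never formed genuinely bears no
setae, and the published correlations are reproduced under this policy.
The `mask` policy excludes those cells from the least-squares fit
entirely (via `als_masked`) and is intended for sensitivity analysis;
on the young reference specimen the two policies agree to within a few
hundredths in the fit correlation.

Fit quality is summarized by the Pearson correlation between observed and
approximated counts over all fitted cells — one point per (limb, group)
pair, zeros included.

## Axial trends

Per-segment setal sums (seven ramal segments: three exopodal, four
endopodal, groups summed within each block, missing as zero) and the
grand total are fitted against the limb number j by ordinary least
squares polynomials. The degree is selected by forward nested F-tests
(statsmodels `anova_lm`): starting from a line, degree k is accepted
while the k−1 → k increment is significant at alpha, and selection stops
at the first non-significant step, so ties favour the smaller model.
Defaults: alpha = 0.05, max_degree = 5. A fit whose residual is
numerically zero (relative tolerance 1e-10) is returned immediately with
a `saturated` flag, since F-statistics beyond it are undefined. The limb
index runs over the printed limb numbers (2..N); limbs with missing
segments can be excluded via a flag, as it is not knowable whether the
original analysis included them.

The published per-segment polynomial table could not be reproduced at
coefficient level under any consistent index convention, and several of
its printed polynomials take values far outside the data range within
their own fitting interval — something a least-squares fit cannot do —
so curve-level agreement with that table is checked but not promised.
The robust, reproducible trend features are asserted instead: the total
setation follows a unimodal quartic with its maximum between limbs 5 and
12, declining monotonically toward the posterior end.

## Cross-specimen comparison

Specimens differ in limb number, so their limb vectors live on different
axes. The query specimen's limb coordinates are mapped affinely onto the
reference's range (first limb to first limb, last to last); values are
not resampled. The pooled (position, x_i) points of both specimens are
then fitted with a single quadratic, which on the two reference
specimens is concave with its maximum in the anterior third of the limb
range, and the query profile, linearly interpolated onto the reference
axis, correlates with the reference profile above 0.95. Per-specimen
limb-vector trends use the same F-test degree selection as the segment
trends.

## Synthetic generator

`SimulationSpec` draws matrices from the model the analysis assumes:
counts around a rank-one mean c·x·y.

- **Limb profile x**: truncated concave quadratic in relative axial
  position t ∈ [0, 1], max(0, 1 − ((t − peak)/width)²), normalized to
  Σx² = 1. Defaults peak = 0.3 (the anterior-third maximum seen in real
  profiles) and width = 0.75 (positive across the whole trunk, as in
  adults, where even the posteriormost segmented limbs carry some setae).
- **Group profile y**: 20 nonnegative weights, normalized. The default
  mirrors the observed heterogeneity: dominant distal groups on both
  rami, a near-empty endopod-proximal segment, moderate spine groups.
- **Scale and size**: defaults n_limbs = 38 and c = 190, the adult
  reference specimen's magnitudes; a young specimen is emulated with
  fewer limbs and smaller c (e.g. 22 and 35).
- **Noise**: `none` (counts are the rounded mean), `poisson`
  (variance = mean), or `rounded-gaussian` with sd σ (rounded, negative
  draws clipped to zero). Rounding, not truncation, so the noiseless
  matrix is within 0.5 of the mean entrywise.
- **Developmental tail**: rules (k, segment labels) blank whole segment
  blocks on the last k limbs, emulating the reduced posterior limbs.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical spec + seed gives a byte-identical
TSV. `recovery_experiment` repeats simulate→decompose, drawing
per-replicate seeds from one generator, and reports bias of ĉ and the
correlations of recovered x and y with truth.

What the generator does *not* emulate: the real counts are sub-Poisson
(developmentally regulated). Poisson noise at realistic magnitudes caps
the observed-vs-approximated correlation near 0.91, below the 0.97–0.98
of the real matrices. Passing recovery tests therefore show the
estimator is unbiased and accurate under generic count noise; they do
not certify the real data's noise model. Molt-by-molt dynamics and the
order of seta addition are out of scope.

## Data conventions

- Canonical format: UTF-8 TSV, first column `limb` with labels like
  `12r`/`12l`, columns `g1`..`g20`; tokens are integers, `(-)` (segment
  absent) and `<int>?` (uncertain count). Parsing and re-serialization
  are token-identical, including reinsertion of discarded duplicate rows.
- Uncertain counts enter the analysis at face value (`1?` → 1, `0?` → 0);
  the flag is retained for reporting.
- When both sides of a limb are listed, the first-listed row is kept and
  the other stored as metadata; toggles expose the terminal bud row and
  the duplicates for sensitivity runs.
- The terminal limb bud is unsegmented, so the whole-block missingness
  structure of segmented limbs does not apply to it; its one or two
  counted elements sit inside otherwise-absent blocks.
- Segment presence is inferred per ramus: a segment counts as present
  iff at least one of its groups has a recorded count (a zero still
  attests the segment). Protopod segments bear no setae and are not
  inferable.

## Known limitations

- The published polynomial-coefficient table is not reproducible from
  the published count tables (see Axial trends); degree selection here
  follows the stated forward nested-F rule rather than attempting to
  reverse-engineer that table's convention.
- Only two specimens ship as fixtures; comparisons of more than two
  specimens are out of scope.
- CLI outputs use 6-significant-digit formatting to keep runs diffable.
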