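# Methods

This note documents the statistical procedures the package implements, the
synthetic data model used to validate them, and the numerical choices made
where the design was genuinely open.

## Evoked responses and responsiveness

Stimulus-evoked ΔF/F is the mean over the 0–1000 ms post-onset response
window minus the mean over the 0–500 ms pre-onset baseline. When
frame-resolved traces are supplied, a frame belongs to a window if its
acquisition interval overlaps it: frame range `[floor(start), ceil(end))`
in frame units, so at 7.5 Hz with onset frame 10 the response window covers
frames 10–17 and the baseline frames 6–9.

Significance per cell and whisker uses a Monte-Carlo permutation test:
trials are shuffled between the whisker and blank sets and the difference
of group means recomputed (default 10,000 iterations). p-values use the
add-one convention (k+1)/(N+1), which avoids p = 0 and is standard for
sampled permutation nulls. Positive and negative responses are two
one-sided tests pooled into one p per stimulus (the smaller tail, its sign
recorded) so there is a single decision per stimulus; Benjamini–Hochberg
FDR at q = 0.05 is then applied per cell across the nine single whiskers.
Tone and all-whisker stimuli are carried through trial filtering but
excluded from receptive-field statistics. A single trial is "responsive"
when its evoked ΔF/F strictly exceeds the blank mean plus one blank SD
(SD with the n−1 denominator).

Implementation note: the permutation shuffle is represented as a boolean
indicator matrix, so a whole null distribution is one matrix product; the
matrix is drawn independently of the data and shared across same-shaped
tests in a batch, which leaves every p-value marginally valid. Ties between
a permuted statistic and the observed one are counted as "at least as
extreme", with a 1e-9 relative tolerance because the vectorized null and
the observed value travel different floating-point paths.

## Tuning statistics

- **BW / eBW.** The BW is the significant-positive whisker with the largest
  mean response (ties broken by smaller p, then fixed whisker order). A
  significant whisker is an eBW when a two-sided permutation test of its
  trials against the BW's trials fails to reject at α = 0.05. The α and the
  absence of multiplicity correction across candidate whiskers are choices
  this package makes explicit (the equivalence criterion is otherwise
  underdetermined); both are configurable.
- **Sharpness** (R_BW − R_W)/(R_BW + R_W) and **CW preference**
  (R_CW − R_W)/(R_CW + R_W) zero negative per-whisker means inside R_W;
  undefined (None) when the relevant numerator response is not positive.
- **CWDI** uses raw, un-zeroed means, which is what allows the diagnostic
  values >1 (negative strongest surround whisker) and <0 (negative columnar
  response); undefined when |R_CW + R_SW| = 0.
- **CoM** is the response-weighted centroid on the 3×3 grid (arc → x,
  row → y with C = 0, D = 1, E = 2; unit spacing), negatives zeroed;
  undefined when no whisker has a positive mean.
- **CW / non-CW class** is conservative: a columnar cell is non-CW-tuned
  only when its BW differs from the columnar whisker *and* the BW response
  is one-sided-significantly greater than the CW response.
- **Rank-ordered curves** sort each cell's nine means descending (negatives
  retained) and average across cells whose BW is the center or a
  center-edge whisker (≥5 sampled adjacent whiskers). `to_max` divides by
  the strongest response. `to_blank` divides by the cell's blank-trial
  evoked SD: the blank evoked mean is ~0 by construction, so it cannot be a
  denominator, and the blank SD expresses the curve in noise-floor units —
  this package's own normalization choice.

## Map geometry

Positions are 2-D µm coordinates in a right-handed frame. "Column radius
along a vector" is the centroid-to-boundary ray-intersection distance (for
a concave histological boundary, the nearest intersection), so normalized
radius 1 is always on the boundary; the 1.25-column-radius inclusion rule
uses the same definition, which is implemented exactly as containment in
the polygon scaled ×1.25 about its centroid. The angular coordinate maps
the eight centroid-to-neighbor-centroid directions onto canonical 45°
sectors by piecewise-linear interpolation, making differently oriented or
sheared fields comparable; the absolute rotation (arc axis → 0°, rows
counted upward C-over-E) is a convention. Ensemble statistics report the
in-column member fraction, the radius distribution, and the circular mean
with resultant length; gradients are ordinary least squares with a
two-sided t-test for non-zero slope.

## Tuning clusters

Similarity metrics for co-columnar responsive pairs: Pearson signal
correlation of zeroed mean-response vectors (undefined for a zero-variance
vector), Euclidean ΔCoM, shared-BW indicator, and magnitude similarity
|R_a − R_b|/|R_a + R_b| on BW responses. Pairs are only formed within one
imaging field. Distance bins are half-open 10 µm bins.

Two nulls:

1. **Spatial shuffle** — cell positions are permuted within each (field,
   column) group, preserving the multiset of positions and of tuning
   vectors, and the binned profile recomputed (default 10,000 iterations,
   percentile 95% CI per bin).
2. **Regression extrapolation** — OLS on pair-level (distance, metric)
   points in 30–200 µm (pair-level rather than bin-mean weighting avoids
   bin-occupancy bias; measured bin-mean fitting is available as a switch
   but calibrates worse), extrapolated to the centers of the bins below
   20 µm; each tested bin's one-sided p is a bootstrap of the within-bin
   pair mean against the extrapolated expectation, BH-corrected across the
   tested bins. Each sub-20 µm bin is tested separately.

Calibration caveat: the excess test compares the bin mean to a *point*
prediction of the fitted line and therefore ignores regression-prediction
error; on data whose distance profile is genuinely nonlinear at short range
(e.g. the curvature of a smooth sub-columnar gradient) it will report
excess, which is detection of real structure rather than a false positive.
Under a position-independent-tuning null the measured per-bin false-flag
rate is at the nominal q (0.045 at q = 0.05 over 200 replicate maps).

The **cluster index** of a cell is its mean signal correlation with
responsive neighbors closer than 20 µm; absent when there is no such
neighbor.

## Longitudinal stability

For a cell responsive in both sessions of a pair:

1. **ΔBW test.** Every whisker significant in session 2 whose mean exceeds
   the prior BW's mean is tested one-sided against the prior BW's trials
   (equivalently: is the prior BW still an eBW?). Any rejection at α means
   the BW changed; the new BW is the strongest significant session-2
   whisker, so a ΔBW flag can only name a whisker that was significant in
   session 2. The candidate tests are uncorrected (configurable), mirroring
   the eBW definition.
2. **ΔCoM bootstrap** (only when the BW is stable). The observed ΔCoM is
   the distance between the two sessions' CoMs computed over whiskers
   sampled in both sessions. The null shuffles each whisker's pooled trials
   between the sessions, preserving per-session counts, and recomputes ΔCoM
   (default 10,000 iterations); changed when the observed value exceeds the
   95th percentile (one-sided at α = 0.05; a two-sided variant is a
   switch).

Responsiveness transitions (stably non-responsive / gained / lost / stably
responsive) use each session's independent FDR-corrected responsive call.
The within-session control splits one session into alternate trials or
halves, recomputes responsiveness per pseudo-session and runs the same
cascade; on stationary synthetic data it flags ≈5% of cells, the nominal
false-positive rate. Interval classes are session-index differences (Δk),
so a cell present in 4 sessions contributes 3 Δ1, 2 Δ2 and 1 Δ3 records;
population fractions subsample one record per cell per class (1000
repetitions, percentile 95% CI).

The change-prediction model is a binomial GLM with logit link on z-scored
covariates — map location (distance from the cell to its session-1 BW
column center, in column radii), tuning sharpness, BW response magnitude
and cluster index (the last omitted for the responsiveness-change outcome)
— with stratified 10-fold cross-validated AUC and per-fold deviance. Cells
without a cluster index receive the population median plus a missingness
indicator. Perfect separation raises an explicit error.

## Synthetic data model

The generator emulates the experimental design so every analysis stage can
be tested against ground truth; it makes no claim to biophysics (no calcium
dynamics, no spike-to-fluorescence model, no behavioral choice model).

- **Map**: nine regular hexagonal columns (apothem 60 µm) on a 140 µm 3×3
  lattice with septal gaps; D2 at the origin, arcs along +x, row C above
  row E.
- **Roster**: cells uniform over the region within 1.25 column radii of any
  column (default 50 cells/column-area); 30% of cells latently responsive.
- **Tuning**: every cell has a latent peak whisker and surface
  `amplitude × decay^d` (d = grid distance; amplitude ~ N(0.5, 0.15²) ΔF/F
  floored at 0.05; decay 0.25, giving sharpness ≈ 0.67 at the column
  center). Among columnar responsive cells 52% take the columnar whisker as
  peak; the rest draw a peak weighted by `exp(−gradient_strength · d_w)`
  toward nearby columns (gradient_strength 0 ⇒ position-independent). A
  cluster field then lets responsive cells within 20 µm of a randomly
  chosen seed cell (25% of responsive cells) adopt the seed's peak with
  probability 0.7 — this produces the sub-20 µm co-tuning excess the
  cluster tests detect. 25% of cells additionally get one suppressed
  whisker with a negative mean (−0.15 × amplitude) to exercise the
  negative-response rules.
- **Trials**: per session, 40 trials per single whisker, 100 blanks, 20
  all-whisker and 20 tone trials in random order; 5% carry a lick flag.
  Whisker-trial evoked ΔF/F = true mean × lognormal gain (σ = 0.25,
  mean 1) + additive Gaussian noise (SD 0.08 ΔF/F); blanks and tones draw
  the additive noise only. The noise form and levels are calibration
  choices — the trial-variability distribution of real data is not
  specified anywhere — set so that ≈30% of cells pass the responsiveness
  test at default trial counts. Passing tests therefore validates the
  statistics under this noise model, not under every conceivable real-data
  noise structure (e.g. correlated noise across cells is not modeled).
- **Drift**: per inter-session interval, each responsive cell shifts its
  peak to a grid-adjacent whisker (same row or arc; the direction is drawn
  only among valid neighbors, never clamped) with probability 0.4 if
  currently non-CW-tuned and 0.05 if CW-tuned; 15% of the remaining cells
  get a bounded BW-preserving surface perturbation (CoM jitter, ±30%
  multiplicative on non-peak whiskers capped below the peak). Because
  shifts re-derive the surface from the new peak rather than accumulating,
  drift is bounded rather than a random walk.
- **Wavering**: responsiveness is gated per session (a responsive cell goes
  silent with probability 0.2; a non-responsive cell expresses its latent
  surface with probability 0.05); gating scales amplitude rather than
  removing the cell, so cross-session registration is untouched.
- **Determinism**: one `numpy` Generator seeded from the config; identical
  config + seed reproduce every output bit-exactly.

## Problem sizes in the validation suite

The statistical validation uses sizes chosen to keep Monte-Carlo error
small while the full suite stays quick: ~500 responsive cells with
2,000-iteration nulls for the type-I calibration of the stability cascade,
1,000 cells for the global-null FDR check, three injected drift fractions
(0.1/0.3/0.5) at ~360 tracked cells each for recovery, pairs pooled over 4
simulated fields (~12,000 pairs, comparable to a pooled multi-field
dataset) for cluster sensitivity, and 200 replicate maps for cluster
specificity.

## Known limitations

- Trial noise is independent across cells; noise correlations and slow
  state fluctuations are absent, so the shuffle nulls are easier here than
  in real data.
- The ΔCoM null conditions on per-whisker trial counts and assumes
  exchangeability across sessions; systematic gain changes between sessions
  (e.g. expression drift) would inflate change calls.
- Histological maps may have concave boundaries; the ray-intersection
  radius uses the nearest crossing, which is a convention.
- The eBW equivalence test is a failure-to-reject criterion and inherits
  its power from trial counts; with few trials, broad tuning is
  over-reported.
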