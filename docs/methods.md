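# Methods

## Model and assumptions

The estimator fits, at every station *i*, the local linear trend model

    Y_ij = β_i0 + β_i t_ij + ε_ij,    ε_ij ~ N(0, σ²) i.i.d.

on log10-transformed, station-wise mean-centered values, by weighted least
squares over *all* observations with bisquare weights

    w_ij = (1 − (d_ij/b_i)²)²  for d_ij < b_i,  0 otherwise,

where `d_ij` is the planar Euclidean distance from the focal station to the
observation's station and `b_i` is the distance to the k-th nearest
observation.  The working assumptions are:

- trends are driven by large-scale phenomena, hence approximately constant
  within a neighbourhood of ~k observations, while *levels* may differ
  arbitrarily between stations (removed by centering);
- errors are independent in space and time.  With 2–3 observations per
  series neither temporal nor residual spatial correlation is estimable;
  both would make the reported standard errors optimistic, which is why
  p-values are interpreted regionally (connected areas of significance)
  rather than station-wise, and left unadjusted for multiplicity.

Distances are Euclidean on projected metre coordinates.  Input that looks
like longitude/latitude (every |x| ≤ 180 and |y| ≤ 90) is rejected with an
instruction to project first; a toy dataset measured in metres within that
envelope would be caught too, which we accept for the safety of the check
(pass `allow_geographic=True` to override).

## Conventions that needed fixing

Several conventions are underdetermined by the general method; the package
fixes them as follows.

- **k counts observations, not stations.**  Co-located observations each
  occupy a distance rank.  A station holding ≥ k co-located observations
  would get bandwidth 0; it is flagged degenerate and excluded rather than
  silently fitted.
- **Strict kernel boundary.**  `w(d = b) = 0`, so the k-th neighbour
  itself carries zero weight and at most k−(ties) observations have
  positive weight.
- **Variance estimate.**  One global `σ̂² = RSS / edf` with
  `edf = n − 2 tr(S) + tr(SᵀS)`, where S stacks each observation's hat row
  evaluated at its own station — the standard GWR effective-degrees-of-
  freedom convention.  The per-station sandwich
  `σ̂² (XᵀWX)⁻¹ XᵀW²X (XᵀWX)⁻¹` gives the standard errors; a per-station
  residual variance is available behind `sigma="local"` for exploration.
- **Cross-validation** leaves out one *observation*: its weight in its own
  station's fit is set to zero, bandwidth ranks untouched, and the
  squared prediction error summed.  Leave-whole-station-out is available
  (`loo="station"`).  Singular leave-out fits are excluded from the sum
  and counted.  The search is an exhaustive, auditable grid (default
  10, 20, …, n); ties go to the smaller k.
- **Tie-breaks** everywhere are stable sorts by (distance, input order);
  argmin ties resolve to the smaller candidate.
- **Numerics.**  Years are internally shifted to the data mid-span
  (`t_ref`, recorded on the result) so the normal equations stay well
  conditioned; intercepts are reported at `t_ref`.  Slopes are invariant
  to this shift (tested to 1e−12).  A local design is declared singular
  when fewer than two observations carry positive weight or the weighted
  variance of t falls below 1e−10 of the squared time span.
- **Significance classes** use strict inequalities: a station is
  `up`/`down` only if `p < α` and the slope has the matching sign;
  `p = α`, zero slopes and invalid fits are `none`.
- **CV screen boundary** is strict as well (`CV > threshold`).
- **Moran's I** uses inverse-distance weights with zero diagonal and *no*
  row standardization by default (`row_standardize=True` available; the
  scheme used is recorded in the result).  The null moments are the
  analytic randomization (kurtosis-corrected) formulas with a two-sided
  normal approximation; the variance requires n ≥ 4.  The row-standardized
  path is verified in the test suite against an independent R
  implementation to 1e−12.

## Centering and its price

Station-wise mean-centering is what makes staggered panels analysable: a
station entering the record late with a high level would otherwise inject a
spurious upward trend into its neighbourhood.  The price is a mild
attenuation: after centering, a common slope β is recovered as
β · Var_within(t) / [Var_within(t) + Var_between(t̄_s)], where t̄_s is a
station's mean observation year.  Under the default 6-panel 2008–2021
design the factor is ≈ 0.95, i.e. a true 0.020 log10/yr is estimated near
0.019.  The test suite asserts exactness (1e−10) in the two situations
where the attenuation vanishes — a single-panel design (all stations share
visit years) and uncentered data with a constant intercept field — and
bounds the bias under rotating panels at < 0.002 log10/yr.  For real data
the attenuation is the accepted cost of robustness to level confounding.

## What the synthetic generator emulates

The generator mimics a national rotating-panel survey: stations uniform
(optionally south-dense with a linear density gradient) over a
500 × 1000 km domain, dealt round-robin into 6 panels after a seeded
shuffle, observed 2008–2021 so each station accrues 2–3 visits; log10
values from smooth intercept/slope fields plus i.i.d. N(0, 0.1²) noise.
Slope magnitudes in the bundled two-region surface (+0.015 west, −0.02
east log10/yr) match the magnitude range such surveys report for organic
carbon.  Injectable outliers shift a station's *first* observation by
+0.8 log10 units, the signature the CV screen exists to catch.

It deliberately does **not** emulate: spatially correlated noise (the
fitted model assumes independence, and silently adding correlation would
make the generator disagree with the estimator's assumptions), uneven
panel sizes from operational disruptions, nonlinear *spatially varying*
trends (the optional `trend_profile` is spatially constant), or stratified
station selection.  Passing tests therefore demonstrate correctness of the
machinery and recovery under the model's own assumptions — not robustness
to correlated errors or design irregularities in real data.

## Problem sizes

Defaults were chosen so a full study is quick on one core: recovery runs
use 800 stations (~1 870 observations, five replicates in a few seconds);
the moving-window and screening analyses 300–1 000 stations.  The engine is
vectorised over stations (an S × n distance/weight matrix), so national
scale (~5 000 stations, ~14 000 observations) fits comfortably in memory
at ~0.5 GB.

## Known limitations

- Standard errors ignore temporal autocorrelation and residual spatial
  correlation and are therefore lower bounds; treat significance maps as
  hypothesis-generating.
- Only time enters as a covariate; no mixed/multiscale extensions, no
  fixed-distance or Gaussian kernels, no robust downweighting of outliers
  (screening is by removal-and-comparison).
- Edge-of-domain stations have one-sided neighbourhoods; their estimates
  are noisier, as the bandwidth column makes visible.
- The two-point change-per-year diagnostic uses only each series' first
  and last observations by design; it feeds the clustering test and is not
  a trend estimate.
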