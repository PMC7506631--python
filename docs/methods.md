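# Methods

This note documents the models, statistics and numerical choices behind
the package, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and compression

A cyclic voltammogram is treated as a vector of currents (µA) over a
triangular potential program (default −0.7 V → +1.2 V → −0.7 V in 424
points; the nominal 10 mV instrument step is metadata — exported trace
lengths do not always match the count implied by the window and step,
so the point count is authoritative).

Traces are compressed to the approximation branch of a discrete wavelet
decomposition.  Defaults: Daubechies order 4 (filter length 8), level 4,
half-point symmetric boundary extension, with the per-level length rule
`L ← floor((L + lf − 1)/2)` — the convention of the MATLAB-era wavelet
toolchain that electronic-tongue work standardized on.  This maps a
424-point trace to 33 coefficients (424 → 215 → 111 → 59 → 33); four
sensors give 132 features, a 92.2% reduction of the 1696 raw currents.
db4/level 4 is the unique standard combination that reproduces those
counts, and both are configurable.

Compression fidelity is reported as the pair (r, fc): the Pearson
correlation and the relative-L2 "fitting coefficient"
`fc = 1 − ‖x − x̂‖/‖x‖` between a trace and its reconstruction from
approximation coefficients alone (detail branches zeroed, inverse
transform truncated to the original length).  The fc definition is this
package's interpretation of the conventional "fitting coefficient";
both acceptance thresholds (r > 0.99, fc > 0.95) are configurable.

## The F clustering factor

Class separation in a score plot is quantified by

    F = [ Σᵢ nᵢ‖z̄ᵢ − z̿‖² / (k−1) ] / [ Σᵢ Σⱼ ‖z_ji − z̄ᵢ‖² / (N−k) ],

the between-class over pooled within-class variance ratio of the score
coordinates — exactly the one-way ANOVA F statistic for scalar
responses (unit-tested against an independent ANOVA routine).  Vector
scores use the squared-Euclidean (trace-of-scatter) generalization,
which reduces to the scalar form in one dimension.  F is undefined (an
error) for fewer than two classes or zero within-class scatter.

The scores default to the first two components of a mean-centered PCA
of the feature block.  Centering only, no autoscaling: the DWT
coefficients share a physical unit (µA-scaled) and autoscaling would
inflate near-zero coefficients.  PCA is computed by SVD with a
deterministic sign convention (the largest-magnitude loading element of
each component is made positive).  CVA — between/within scatter
maximization after a PCA pre-projection (up to 99% cumulative variance,
capped at n − k components) — is available as an alternative score
model for visualization.  The elimination uses PCA scores: the
in-sample CVA criterion is nearly monotone in the feature set (adding
channels cannot decrease the fitted discriminant ratio), so leave-one-
sensor-out differences under CVA reflect overfitting noise rather than
sensor quality.

Cluster ellipses on score plots are Mahalanobis contours of each
class's 2×2 score covariance at the chi-square(2 df) quantile of the
confidence level (default 95%) — the population form customary in
ET score plots; with 5 replicates per class a small-sample Hotelling
form would be defensible too.

## Backward elimination of sensors

Each iteration computes the reference F of the current roster, then F
with every sensor excluded in turn (scores refit from scratch per
candidate; the DWT coefficients are sensor-local and computed once).
The exclusion with the highest F (ties broken by roster order) is
accepted when it reaches at least `(1 − tolerance_frac)` of the
reference.  The default tolerance of 2% also admits removals that leave
F essentially unchanged — an "inclusion does not demote the system"
removal; `tolerance_frac = 0` demands strict non-decrease, which makes
the reference-F sequence non-decreasing by construction.

`min_sensors` defaults to `n_analytes + 1` (at least 2).  Two reasons.
Practically, an array cannot quantify m analytes with fewer than m
channels, and one extra channel is the usual margin against background
and drift.  Statistically, at desk-scale replication (5 replicates ×
4 classes) the within-class scatter of the 2-D scores is estimated from
only (N − k)·2 = 32 degrees of freedom and fluctuates by ~25% (χ²)
between candidate rosters — the same magnitude as a single informative
sensor's between-class share (~25% is the ceiling for four balanced
sensors).  The F-decay stop alone therefore overshoots by one sensor in
a substantial fraction of noise realizations, under any honest noise
model we examined; the floor makes the endpoint robust while the decay
rule still governs everything above it (and is exercised by tests with
a lower floor).

## Synthetic voltammograms

Each sensor is a `SensorResponseSpec`: per-analyte sensitivity
(µA/µM), anodic peak potential and Gaussian width; a linear baseline; a
Langmuir-type saturation constant (∞ = linear); additive white noise
per point; a per-measurement multiplicative response fluctuation; and a
current drift linear in acquisition order.  A trace is the baseline
plus anodic Gaussians on the forward branch, mirrored negative cathodic
peaks (shifted −0.06 V, default half magnitude — quasi-reversible
behavior) on the reverse branch, noise and drift.  With noise off the
generator satisfies exact closed forms (peak height = sensitivity ×
concentration; superposition of mixtures), which the tests assert.

Defaults emulate the pharmaceutical study case: stocks at 250 µM in
5 replicates plus buffer blanks; mixture designs over 0–500 µM (PA,
UA) and 0–2000 µM (AA); anodic peaks near +0.39 V (PA), +0.01 V (AA),
+0.30 V (UA); peak width 0.16 V (broad enough that level-4
approximation coefficients retain r > 0.99 / fc > 0.95, as real CV
peaks at 100 mV/s are).  Samples are acquired in interleaved rounds
(one replicate of every class per round) so drift inflates
within-class scatter the way session drift does in practice.

`default_array_specs` plants ground truth for recovery experiments:

- *informative* sensors (4): distinct cross-sensitivity patterns of
  common slope-vector norm — three follow published calibration slopes
  of ZnO-, Prussian-blue- and polypyrrole-modified composite
  electrodes, the fourth is a flat noble-metal-like pattern —
  differentiated mainly through per-sensor peak-position jitter
  (±0.15 V); noise 0.2 µA, negligible drift.  The common norm matters:
  raw published slopes are nearly proportional across electrodes and
  span an order of magnitude, which would make "informative" units
  mutually redundant at the score level and the recovery ground truth
  ill-posed.
- *redundant* sensors (2): 0.7-scaled copies of an informative parent
  burdened with strong session drift (0.5 µA/sample).
- *noisy* sensors (2): near-zero sensitivities, 2 µA noise, strong
  drift.

With this construction the within-class scatter at the reduced-array
stage is dominated by isotropic additive noise, whose projection onto
the score plane is roster-independent, so removing an informative
sensor reliably lowers F by its between-class share while removing a
planted bad sensor raises it — the property the selection-recovery
acceptance test measures (≥ 90% exact recovery over 20 seeded
replicate campaigns).

What the simulator does *not* reproduce: electrochemical kinetics
(Butler–Volmer, ohmic drop, capacitive charging), peak asymmetry and
potential shifts with concentration, fouling memory effects, and
correlated inter-sensor noise.  Passing tests demonstrate that the
algorithms behave as specified under the assumed statistical structure,
not that a particular laboratory array would yield the same F values —
those are data-bound.  Simulated F magnitudes at the clean-array stage
are far larger than laboratory ones because real replicate scatter has
structured components the generator only partially emulates.

The "tilted" factorial design is realized as an equispaced grid whose
point levels are offset by `tilt_fraction × spacing × u`, with `u` an
index-derived value in [−1, 1] from an irrational rotation — 
deterministic without a seed, no two samples share an exact level, and
`tilt_fraction = 0` recovers the exact grid.  Outputs are clipped to
the design bounds.

## ANN calibration

The quantification model is a single-hidden-layer perceptron with
Matlab-nomenclature transfers (`purelin` identity, `tansig` tanh,
`logsig` logistic, `satlins` = clamp(x, −1, 1)); the reference topology
is 6 hidden `purelin` neurons and a `satlins` output per analyte.
Inputs are z-scored per feature with training statistics; targets are
affinely mapped to [−0.9, 0.9] per analyte, which keeps `satlins` in
its linear region during training while preserving its clamping role —
predictions cannot leave the calibrated domain by more than the affine
margin.

Training is deterministic: seeded uniform initialization in
[−init_scale, init_scale] (default 0.01) and full-batch MSE
minimization with analytic gradients under L-BFGS (max_iter 2000, ftol
1e−8).  Two defaults matter in the features ≫ samples regime
(132 coefficients, 27 training mixtures):

- the *small initialization*: gradient-based training started near zero
  stays close to the minimal-norm interpolant, the implicit
  regularization that makes an exactly-fitting linear network
  generalize;
- the *relative variance floor* (default 1e−2): input columns whose
  training standard deviation is below 1% of the largest column's are
  dropped as degenerate (with a warning).  Coefficients from flat trace
  regions vary only by measurement noise; per-feature z-scoring would
  amplify them into unit-variance pure-noise inputs which an
  interpolating network then loads on, and test-set accuracy collapses
  independent of the noise level.  The floor generalizes zero-variance
  column removal to "no usable signal" columns; `variance_floor = 0`
  restores the permissive behavior.

With identity transfers the network's global optimum coincides with
ordinary least squares on the scaled data, which the tests assert
against a `lstsq` oracle in an overdetermined setting.  Topology search
trains every candidate with the same seed policy and ranks by total
test RMSE — test-set reuse for model selection is the conventional ET
protocol and is reported as such.

## Evaluation statistics

- Calibration: OLS of blank-subtracted maximum peak height vs.
  concentration; `s_yx = sqrt(SSE/(n−2))`; LOD = 3·s_yx/slope (NaN for
  non-positive slopes).
- Comparison regression: OLS of predicted on expected concentration;
  half-confidence intervals via t(n−2); RMSE is the prediction error
  against the identity line (not the regression residual), the
  chemometric convention for obtained-vs-expected tables.
- EJCR: the point (slope₀, intercept₀) lies inside the joint region iff
  `n·Δa² + 2Σx·Δa·Δb + Σx²·Δb² ≤ 2s²·F(2, n−2; confidence)` with a the
  intercept and b the slope; s² = 0 degenerates to an exact-equality
  test.  Containment of (1, 0) means no statistically detectable bias.
  Coverage is verified by simulation (95% ± 3% over 500 replications).
- NRMSE: `sqrt(Σ(ŷ−x)² / Σx²)` over all samples and analytes — a
  global L2 normalization, one of several definitions in circulation;
  treated as a package convention, not a literature-comparable figure.
- Repeatability: RSD% = 100·sd/mean (sample sd) of consecutive peak
  heights; < 4% is the customary stability bound.

## Workflow reproducibility

`run_full_workflow` derives per-stage seeds from the global seed by a
fixed affine map, so stages are independently reproducible; artifacts
are JSON/CSV with sorted keys and no timestamps, making a rerun with
the same config byte-identical (asserted by the acceptance suite).  The
run log records the package version, global seed, per-stage seeds and
a SHA-256 hash of the canonical config serialization.  Config files are
YAML mirroring the dataclasses, validated by the dataclasses'
constructors.

## Problem sizes

The test and acceptance suites run at the study's native desk scale:
424-point traces, 8-sensor arrays, 20-sample selection campaigns,
27 + 11 mixture designs, 20 seeded replications for recovery, 500 for
EJCR coverage.

## Known limitations

- The F-decay stopping rule is statistically fragile at 5 replicates
  (see above); the array-size floor is the package's mitigation.
- The simulator's within-class noise model (isotropic additive +
  multiplicative amplitude + linear drift) is a deliberate
  simplification; F magnitudes are not comparable to laboratory values.
- `satlins` has zero gradient outside [−1, 1]; targets scaled into
  [−0.9, 0.9] avoid dead saturation at initialization, but custom
  scalings that start saturated may not train.
- EJCR uses the classical homoscedastic OLS form; heteroscedastic
  prediction errors (larger at high concentration) are not modelled.
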