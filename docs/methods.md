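# Methods

This note documents the models, numerical choices, and known limits of the
package. It states nothing that the test suite or `scripts/acceptance.py`
does not itself compute.

## Single-voxel autocorrelation

The per-voxel statistic is the unbiased lagged autocovariance divided by the
biased lag-0 variance: `c(k) = Σ x̃(t)x̃(t+k)/(N−k)`, `r(k) = c(k)/(Σ x̃²/N)`.
The unbiased scaling divides each lag's product sum by the number of
overlapping samples; combined with the biased lag-0 denominator this matches
the "unbiased cross-correlation" convention of standard signal-processing
routines, so `|r(k)|` may slightly exceed 1 at small `N` (bounded by
`N/(N−k)`). Values are reported as computed and never clamped — an asserted
invariant rather than a silent correction. Series are demeaned by default
(`demean=False` is available; the convention is not universal across
toolboxes). Lags are capped at a 4-second total shift (`floor(4/TR)`,
minimum 1): beyond that window gray-matter BOLD autocorrelation is not
distinguishable from noise, and at TR = 2 s the lag vector has exactly two
entries. Constant (zero-variance) voxels raise or are excluded and logged,
never imputed.

## Signal conditioning

Conditioning runs in a fixed order — nuisance regression (with spike
columns), then zero-phase low-pass filtering, then autocorrelation — because
filtering after regression is what the lagged products should see, and
frame *deletion* would corrupt lagged structure. Flagged frames are removed
by one-hot spike regressors instead, which zeroes their residuals exactly
while keeping the time axis contiguous.

* CompCor-style components: leading right singular vectors of the demeaned
  noise-ROI (white matter/CSF stand-in) voxel × time matrix; default k = 5,
  truncated with a warning when rank is lower.
* Scrubbing flags: |z| ≥ 3 of the global signal, or frame-to-frame
  realignment differences > 1 mm translation or > 0.05 rad rotation. The
  frame-difference convention (not absolute displacement) follows standard
  artifact-detection practice; both thresholds are parameters. A constant
  global signal contributes no flags (guarded division).
* Low-pass filter: forward–backward 4th-order Butterworth, cutoff 0.09 Hz
  default, per-voxel mean re-imposed exactly; a rectangular FFT dialect is
  selectable since the exact legacy filter of the original toolchain is not
  standardized. Zero-phase filtering matters: phase distortion would bias
  lagged products.
* Whether motion parameters themselves join the design is a config choice
  (`build_confounds(..., motion=...)`); the default design is components +
  spikes only.

## Clustering and role labels

Distances between lag vectors are max-normalized into similarities
(`S = 1 − D/max D`, diagonal 1, per-individual normalization), defining a
complete weighted graph with zeroed self-loops — no sparsification
threshold, resolution fixed at 1.0 (both exposed). Multilevel Louvain
(igraph) maximizes modularity; because the optimizer is order-dependent, it
is restarted `n_restarts` times (default 20) from seeded RNG states and the
best-modularity partition is kept, making results reproducible given the
seed. The one-community partition (Q = 0) is the floor, so reported
modularity is never negative. A resolution sweep was evaluated and rejected:
on this dense, offset-weight graph the partition count is extremely
sensitive to resolution (γ = 1.2 already shatters the graph into hundreds of
communities), so γ = 1.0 is the only usable default.

Roles are assigned by ranking clusters on mean lag-1 autocorrelation:
rank 1 = anterior-medial, last = posterior-lateral, rank 2 = intermediate
when three or more clusters exist; ties (within 1e-12) break by cluster
size, then lowest label. Rank labeling reproduces the anatomical ordering of
the long-axis gradient without requiring an atlas. Maps with a cluster count
different from the expected three are flagged and excluded from group
averaging and group statistics (configurable), mirroring how non-conforming
individuals are handled in practice. Group-level maps cluster the
elementwise mean of members' similarity matrices; the group autocorrelation
map used for role-ranking the group clusters is the members' mean map.

## Preservation, surrogates, nulls

Preservation is the per-role Jaccard coefficient between an individual's
role voxel set and the reference (control) group's, computed per role and
hemisphere; a missing role yields a missing value, not zero. Reliability is
the pairwise per-role Jaccard among a group's individuals.

Null thresholds come from surrogate maps that preserve spatial
autocorrelation while destroying voxel-level specificity. The generator is
volumetric variogram matching — appropriate for a volume like the
hippocampus where sphere-rotation ("spin") tests do not apply:

1. one shared random permutation of voxels, applied to all lag columns
   jointly (preserving each voxel's joint lag-1/lag-2 signature, since
   clustering consumes the vector);
2. Gaussian distance-kernel smoothing of the permuted map, the kernel scale
   chosen per surrogate from quantiles of the inter-voxel distance
   distribution by minimizing the squared mismatch between the surrogate's
   and the original's binned lag-1 variograms (25 equal-count bins);
3. rank-remapping of each lag column back onto its original value multiset,
   so surrogate values are exactly the original values rearranged.

Each surrogate is clustered and role-labeled exactly like real data — role
matching uses the same autocorrelation-rank rule, deliberately not optimal
(Hungarian) assignment, which would bias the null upward. The 95th
percentile of surrogate Jaccards per role is the replication threshold;
thresholds are recomputed per cohort because they are data-dependent.
Defaults: 1000 surrogates (100 in bounded test settings), 25 variogram bins.
Rank-remapping a strongly multimodal value distribution re-amplifies
mid-rank noise, so individual surrogates' variogram fits vary; fidelity is
assessed on the mean variogram correlation across surrogates.

## Statistics layer

Cell means (one row per participant × hemisphere × role; lag-1 by default,
mean-of-lags selectable) feed a linear mixed model with full-factorial
cluster × group × hemisphere fixed effects (sum coding, so term tests are
Type-III) and a participant random intercept, fit by REML through
statsmodels. Term F statistics are Wald quadratic forms on the REML
fixed-effect covariance with containment denominator degrees of freedom:
between-subject terms use `n_subjects − g` and within-subject terms
`N − n_subjects − (p − g)` (`g` = between-subject cells, `p` = fixed-effect
columns). For balanced designs these equal the classical split-plot df, and
the null simulation in the acceptance suite verifies the resulting tests are
calibrated (type-I within [0.025, 0.075] at α = 0.05 across all seven terms;
a 1000-replicate check during development measured 0.046–0.060).
Kenward-Roger is not available in the host machinery; `df_method` records
what was used. Post-hoc pairwise contrasts of estimated marginal means use
the studentized-range (Tukey) correction, with simple-effects contrasts
available within levels of another factor.

Correlation families (preservation vs lateralized memory scores) are
declared explicitly and adjusted with Benjamini–Hochberg; the family is
exactly the supplied list — silent inflation is not possible through this
interface. The epileptogenic/healthy hemisphere recoding maps each patient's
hemisphere factor through their seizure focus and excludes controls by
default. MTS-status models reuse the same mixed-model machinery via
`mts_cells`, which annotates patient rows with sclerosis status and applies
the standard exclusions (controls always; unconfirmed "possible" cases by
default).

## Synthetic cohort generator

Each ROI voxel follows AR(1) dynamics `x_t = φ_v x_{t−1} + ε_t` with 50
burn-in frames; AR(1) is the minimal process with a controllable
lag-1/lag-2 signature (`r(k) → φ^k`). Defaults: T = 180 volumes at
TR = 2 s; two mirrored ellipsoidal masks (~1100 voxels each on the default
32×32×20 grid of 2 mm voxels); three latent bands cut at rank-terciles of a
composite axis (0.7 × anterior-posterior + 0.3 × medial-lateral position),
so band sizes match to within one voxel; out-of-mask voxels are white
noise; innovation SD 1 (the statistic is scale-invariant). Motion traces
are slow random-walk drift plus injected >1 mm spikes (rate 0.01/frame).

Band AR coefficients default to (0.80, 0.50, 0.00), anterior-medial first.
These were calibrated to the generator's defining requirement: data in
which the similarity + modularity method recovers three clusters in every
individual of every group, as observed in real hippocampal cohorts. Two
constraints drive the values: the lag-1 estimator SD at T = 180 is
~0.065–0.075 (Bartlett), so adjacent bands need gaps of ≳0.3 for the
three-community partition to dominate the two-community merge in
modularity; and the boosted anterior coefficient inflates the maximum
distance used for similarity normalization, compressing the
intermediate/posterior contrast, so the posterior band sits at 0 — the
"autocorrelation indistinguishable from noise" regime that is the natural
short-timescale end of the gradient. The LTLE-like group adds +0.15 to the
anterior-medial φ, bilaterally by default (`boost_bilateral=False` makes it
unilateral); its magnitude is a test convenience, not an empirical estimate.
A smooth-gradient mode replaces the discrete bands for robustness checks and
carries no truth labels.

Memory scores are generated after the analysis has run, as
`score = slope · J_am + Normal(0, σ²)` on each patient's *realized*
anterior-medial preservation — verbal scores from the left hemisphere of
the LTLE-like group, visuospatial from the right hemisphere of the
RTLE-like group, all other scores pure noise — so the lateralized
correlation layer has a known generating slope and hemisphere to recover.
`memory_noise_for_target_r` converts a target population correlation into
the noise SD.

What the generator does *not* emulate: hemodynamic forward models,
physiological noise spectra, scanner drift, spatial smoothness of
neighboring voxels (each voxel's innovations are independent), atlas-shaped
anatomy, and between-subject variance beyond sampling noise. Passing tests
therefore demonstrate that the machinery recovers planted temporal
structure and that the inference layer is calibrated — not that effect
sizes or thresholds transfer to real data. In particular the surrogate
null thresholds and preservation values here are far higher than those seen
with real cohorts, because synthetic individual maps are much more similar
to each other than real ones.

## Problem sizes and determinism

Tests and the acceptance script use reduced problem sizes chosen as the
smallest that still exercise each property: ~330-voxel masks (20×22×14
grid) for cohort-level checks, ~620-voxel masks for surrogate fidelity, 12
replicate cohorts for the power check (the planted interaction is so large
that power is effectively 1), 400 direct cell-table replicates for null
calibration, and 100–200 replicates for order-statistic and correlation
recovery checks. All randomness flows from explicit seeds: cohorts spawn
per-participant child streams from one root seed, clustering restarts from
a recorded seed, and the acceptance script derives every stream from its
`--seed` argument.

## Known limitations

* Modularity on the max-normalized complete graph has a resolution floor:
  band separations well below ~4 estimator SDs merge communities, and the
  max-distance normalization couples a single outlier pair to the whole
  similarity scale.
* Containment df are exact only for balanced designs; with excluded maps the
  tests become approximate (the direction of the approximation is mild for
  small imbalance).
* The unbiased autocorrelation estimator is biased downward at finite N
  (≈ −(1+4φ)/N at lag 1); band recovery tolerances account for this.
* Jaccard preservation compares hard labelings; partial-volume or soft
  assignments are out of scope.
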