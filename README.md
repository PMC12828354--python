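# svautocorr

Single-voxel BOLD autocorrelation mapping, autocorrelation clustering, and
cluster-preservation statistics for hippocampal resting-state fMRI.

## The problem

The hippocampus is not temporally uniform: the intrinsic timescale of its
BOLD signal falls along a gradient from the anterior-medial to the
posterior-lateral end. Measuring that organization per voxel — and how it is
disturbed in unilateral temporal lobe epilepsy (TLE) — requires a pipeline
that (1) quantifies each voxel's timescale, (2) segments the structure into
data-driven clusters, (3) scores how well a patient's cluster layout is
preserved relative to a normative group, against a null that respects
spatial autocorrelation, and (4) relates preservation to memory performance.
This package implements that pipeline for researchers analyzing hippocampal
ROI time series, together with a synthetic cohort generator so every stage
is testable without patient data.

## The statistic

For a voxel series `x` of length `N` (demeaned as `x̃`), the lag-`k`
single-voxel autocorrelation is the unbiased lagged product sum normalized
by the biased lag-0 variance:

    c(k) = 1/(N−k) · Σ_{t=1}^{N−k} x̃(t)·x̃(t+k)
    r(k) = c(k) / ( 1/N · Σ_t x̃(t)² )

Lags are capped so the total shift never exceeds 4 s (2 lags at TR = 2 s),
the window over which gray-matter BOLD autocorrelation remains
distinguishable from noise. Each voxel therefore carries a lag vector
`[r(1), …, r(k_max)]`.

Downstream, pairwise Euclidean distances `D` between lag vectors become a
similarity matrix `S = 1 − D/max(D)`; Louvain modularity optimization on the
complete weighted graph yields the clusters (the number of clusters is
estimated, not preset); clusters are ranked by mean `r(1)` into
anterior-medial / intermediate / posterior-lateral roles. Preservation of an
individual map against a reference group map is the per-role Jaccard
coefficient `J(A,B) = |A∩B|/|A∪B|`, thresholded at the 95th percentile of a
surrogate-map null (variogram-matched surrogates: permute → distance-kernel
smooth → rank-remap). The statistics layer fits a linear mixed model
(cluster × group × hemisphere, participant random intercept; Tukey-corrected
contrasts) and Benjamini–Hochberg-corrected Pearson correlations between
preservation and lateralized memory scores.

## Worked example

```python
import svautocorr as sv
from svautocorr.pipeline import analyze_cohort
from svautocorr.stats import fit_lme

spec = sv.SimSpec(n_per_group=6, grid_shape=(20, 22, 14), seed=42)
sim = sv.simulate_cohort(spec)           # 18 participants, 2 ROIs each
result = analyze_cohort(sim, seed=42)    # autocorr -> clusters -> preservation

print(result.cells.groupby(["group", "role"])["mean_autocorr"].mean().round(3))
lme = fit_lme(result.cells)
print(lme.anova.round(3).to_string(index=False))
```

prints

```
group    role
control  anterior-medial      0.761
         intermediate         0.482
         posterior-lateral    0.005
ltle     anterior-medial      0.926
         intermediate         0.492
         posterior-lateral    0.010
rtle     anterior-medial      0.757
         intermediate         0.480
         posterior-lateral    0.010
Name: mean_autocorr, dtype: float64
                 term         F  df_num  df_den     p
                 role 59998.785       2      75 0.000
                group   350.462       2      15 0.000
           hemisphere     0.209       1      75 0.649
           role:group   348.348       4      75 0.000
      role:hemisphere     0.767       2      75 0.468
     group:hemisphere     0.453       2      75 0.638
role:group:hemisphere     0.402       4      75 0.807
```

Reading the output: cluster-mean lag-1 autocorrelation decreases strictly
across the three roles in every group (the long-axis gradient); the
LTLE-like group's anterior-medial mean is elevated (0.926 vs 0.761) in both
hemispheres, which surfaces as the large cluster × group interaction, while
hemisphere and its interactions are null — exactly the structure the
generator plants.

A thin CLI wraps the same machinery:

```sh
svautocorr simulate --out cohort/ --seed 1 --n-per-group 20
svautocorr run --out results/ --seed 1 --n-per-group 8 --no-prep
```

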