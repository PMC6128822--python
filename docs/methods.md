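# Methods

## Scope and data model

`cuetopo` analyses the spatial topography of individual-subject fMRI
cue-reactivity peaks ("hotspots") and their proximity to scalp stimulation
sites. All coordinates are RAS MNI millimeters; voxel indices are 0-based;
volumes carry a NIfTI-style 4×4 voxel→mm affine. The unit of all downstream
analysis is the hotspot: one subject's local-maximum voxel inside a
cluster-corrected activation cluster, tagged with drug group, sex, peak t,
cluster size, and cluster rank.

## Block paradigm and first-level model

The task model is a 12-minute block design: six 120-s epochs of alternating
24-s blocks of Drug, Neutral, Blur and Rest conditions (five 4.8-s pictures
per block). Four 24-s blocks fill only 96 s of each 120-s epoch; the task
description does not say how the remaining 24 s were occupied, so this is a
configuration choice (`epoch_fill`): the default `rest_gap` leaves the final
24 s of each epoch as unmodeled rest; `cycle` keeps cycling condition slots
(five per epoch). Either way the Drug and Neutral regressors are identical
in count and spacing, which is what the contrast depends on.

Condition regressors are boxcars convolved with a canonical double-gamma HRF
(peak delay 6 s, undershoot delay 16 s, peak:undershoot ratio 6, dispersion
1 s, unit-peak scaled) on a 0.1-s grid and sampled at volume times
`t = i·TR` (TR default 2.2 s; no slice-timing model). Rest is the implicit
baseline; Drug, Neutral and Blur are modeled, with the contrast
Drug − Neutral. Six motion covariates and an intercept complete the design;
all-zero motion columns are dropped (and recorded) to keep the design full
rank. Estimation is per-voxel ordinary least squares — no temporal
autocorrelation model (a deliberate simplification relative to SPM's default
prewhitening; with a noise simulator that is temporally white, OLS is the
correct model, and the t-statistics calibrate exactly, which the null-
simulation tests verify). `df = n_volumes − rank(X)`. Voxels with zero
residual variance up to roundoff get a finite sentinel t (1e6) and are
counted in `degenerate_voxels`. The second level is a one-sample t across
subject contrast maps with `df = n − 1`.

## Cluster-extent correction

Activation is defined one-sided (positive t, since hotspots are elevations),
thresholded at voxel `p < 0.005` by default, and grouped into connected
components (default 6-connectivity, i.e. shared faces; 18 and 26 are
options). The minimum cluster extent is derived by Monte-Carlo simulation:
white Gaussian fields on the mask's bounding grid are smoothed to a target
Gaussian FWHM, re-standardized, thresholded at the same voxel p, and the
largest in-mask component size recorded per iteration (default 1000). The
extent threshold is the smallest k whose empirical exceedance probability
`P(max size ≥ k)` is at most the cluster α (default 0.05). Surviving
clusters are annotated with their empirical cluster-level p from the stored
null distribution. Only a Gaussian-shaped autocorrelation is simulated; the
mixed-model (Gaussian + exponential) ACF of the 2017 3dClustSim revision is
not implemented. Consequently the published 48-voxel extent for the original
acquisition is treated as a worked-example constant, not a number this
package re-derives (the smoothness estimated from the original residuals was
never reported).

Mask dilation is iterative 3D binary dilation. The atlas GUI that inspired
the option labels its setting "2D dilation"; since the masks here are 3D
volumes, dilation is 3D, and the iteration count (e.g. 3) is configuration.

## Hotspot extraction

Clusters are ranked by ascending cluster-level p — equivalent to descending
extent under a shared null — with descending peak t and then lexicographic
peak index as tie-breaks. For each surviving cluster the hotspot is the
member voxel with maximal t (ties broken lexicographically, so extraction is
deterministic), converted to MNI mm. Subjects with no surviving cluster are
non-responders and contribute no points. Cohort sets come in two modes:
`full_complement` (every surviving cluster) and `one_per_individual`
(rank-1 hotspots only); the second is always a multiset subset of the first.
No cap is placed on clusters per subject by default.

## Topography: two-phase k-means with silhouette-selected k

Clustering operates on raw MNI coordinates in mm, unweighted, Euclidean.
One fit at a given k:

1. **k-means++ seeding** — first centroid uniform over points, each next
   drawn with probability proportional to squared distance to the nearest
   chosen centroid.
2. **Batch phase** — Lloyd iterations (assign to nearest centroid, move
   centroids to member means) until assignments stop changing or the WCSS
   improvement falls below 1e-10 mm² (cap 100 iterations). Empty clusters
   are repaired by donating the point currently farthest from its centroid.
3. **Online phase** — repeatedly apply the single best point move, using the
   exact WCSS change for moving point i from cluster a (size nₐ) to b:
   `Δ = n_b/(n_b+1)·d²(i,c_b) − nₐ/(nₐ−1)·d²(i,cₐ)`; stop when no move
   helps (cap 100 moves). Centroids update incrementally, with a final exact
   recompute. WCSS is asserted non-increasing in both phases.

The whole fit is restarted 1000 times (default) with fresh seeding; the
minimal-WCSS restart wins, ties going to the lowest restart index. k is
scanned over 2–10 and selected by maximum mean silhouette
(`s = (b−a)/max(a,b)`; singletons and the all-coincident-points case score 0
by convention), ties to the smaller k. A winning mean silhouette below 0.25
flags the solution as "weak structure" — a documented convention, not a
failure. A per-cluster/alternative selection statistic was considered and
rejected to keep one scalar criterion; the per-k diagnostics table is always
retained so any other rule can be applied post hoc.

Post-hoc balance tests are Pearson χ² (no continuity correction) on
factor × cluster count tables for drug group and sex, with a warning flag
when any expected cell is below 5.

## TMS coverage

Distances from hotspots to electrode positions are straight-line 3D mm (the
analysis is explicitly Euclidean, not along-scalp geodesic). Coverage of
electrode e at radius r is `100·|{hotspots with d ≤ r}|/n`, computed at
20/30/40/50 mm by default (2–5 cm, the usual span of rTMS effective depth).
The "best" electrode per radius maximizes coverage; ties are declared after
rounding percentages to integers (matching reports that print whole
percents; exact-count tie-breaking is available) and reported jointly
("FPz/FP2"). Counting is per-electrode (a hotspot can be within r of several
electrodes); nearest-electrode attribution can be recovered from the
distance matrix if wanted.

**Electrode coordinates.** No specific published digitization is bundled.
The builtin table is a *synthetic* 10-10 (+ the 10-5 intermediates AF5/AF6
etc., so labels like AF5 resolve) digitization computed from the fractional
arc rules of the 10-10 system on an ellipsoidal scalp model whose center and
semi-axes are fitted so the vertex (~(0,−14,95)), frontal pole (~(0,88,−5)),
temporal points (~(±84,−14,−5)) and occipital pole land at plausible MNI
scalp positions. It is adequate for method development and the package's
tests; conclusions about specific electrodes on real data should use a real
digitization passed as a CSV (`label,x,y,z` in MNI mm), which is then carried
as provenance in every report.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes.

Coordinate level: hotspot loci are drawn from a three-component isotropic
Gaussian mixture with centroids (7, 50, 4), (−40, 24, 25), (30, 18, 41) and
weights 0.40/0.32/0.28 — medial prefrontal/ACC, left and right lateral
prefrontal concentrations. The within-component dispersion is not something
the cohort literature states; the default of 12 mm makes components overlap
yet remain silhouette-separable, which is the regime the analysis is
designed for. Group sizes default to 55/48/53 (cocaine/nicotine/alcohol) and
the responder rate to 103/156 ≈ 0.66. Responders carry one true locus; in
coordinate mode they contribute `1 + Poisson(1.53)` hotspots (matching a
261-points-from-103-responders ratio), rank 1 at the true locus. Sex labels
are drawn with the per-group male fractions of the emulated cohort.

Image level: a subject's 4D series is
`y(v,t) = 100·(1 + amplitude/100 · blob(v) · reg(t)) + noise(v,t)` on a 3 mm
frontal bounding-box grid (x −60..60, y −6..90, z −24..60 mm), where `blob`
is a unit-peak Gaussian at the true locus and `reg` the unit-peak
HRF-convolved Drug regressor. Noise is white Gaussian smoothed to 8 mm FWHM
(the data are modeled as already preprocessed and smoothed) and rescaled to
`noise_sd`. Defaults: amplitude 1.0% signal change and noise sd 1.0% of
baseline — typical block-design BOLD magnitudes — giving a peak
contrast-to-noise of 1.0. The blob default is 14.4 mm FWHM: a ~12 mm
activation focus observed through the 8 mm preprocessing kernel
(√(12²+8²)). Not simulated: scanner drift and physiological noise, motion,
temporal autocorrelation, anatomical variation, non-Gaussian activation
shapes, and the visual-control conditions beyond regressor placement.
Passing tests on this generator therefore demonstrate internal consistency
and correct calibration of the pipeline, not performance on real data.

## Numerical and reproducibility choices

- Every random operation takes an explicit seed; pipeline stages derive
  independent substreams from one base seed via `SeedSequence.spawn`, so
  reports regenerate byte-identically from the same configuration.
- Cluster records sort deterministically (size, peak t, lexicographic index);
  hotspot peak ties break lexicographically; restart ties break by index.
- Zero-residual GLM voxels are detected relative to the per-voxel data scale
  (`se ≤ 1e-12 · rms`) and sentineled rather than returning ±inf.
- Table io round-trips doubles exactly (`%.17g` out, round-trip parsing in).
- Radii given in cm in configuration are normalized to mm at validation.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic data sized
for a single CPU: 261-point coordinate cohorts for the clustering scan
(k = 2–10 × 1000 restarts, ~20 s), 20³ masks × 1000 iterations for the
extent-threshold calibration, and a 12-subject image-level demonstration
(41×33×29 voxels × 327 volumes each) for the end-to-end recovery check.
These sizes were chosen so the whole suite completes in about a minute while
keeping every statistical check at meaningful power.

## Known limitations

- Gaussian-ACF nulls only; real fMRI noise has heavier-tailed spatial
  autocorrelation, so extent thresholds for real data should come from tools
  fitting a mixed ACF.
- OLS without prewhitening overstates first-level df on real (temporally
  autocorrelated) data.
- The builtin electrode table is a geometric model, not a digitization.
- Silhouette-based selection with a single scalar criterion can be
  insensitive when clusters are highly unbalanced; inspect the per-k
  diagnostics rather than trusting the selected k blindly.
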