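# cuetopo

Spatial topography of fMRI drug-cue reactivity "hotspots", and how well fixed
scalp locations would cover them as neuromodulation targets.

## The problem

Substance-dependent individuals (cocaine, alcohol, nicotine) show elevated
BOLD responses to pictures of their drug relative to matched neutral
pictures. Group maps hide large individual variability in *where* that
response peaks — which matters when the peak is a candidate target for
transcranial magnetic stimulation (TMS). `cuetopo` implements the full
individual-variability analysis chain:

1. **First-level GLM** — per-subject block-design analysis (Drug vs Neutral
   contrast, canonical double-gamma HRF, 6 motion covariates, per-voxel OLS,
   `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`, `df = n − rank(X)`).
2. **Cluster-extent correction** — one-sided voxel threshold `p < 0.005`,
   connected-component labeling (6/18/26-connectivity), and a Monte-Carlo
   minimum cluster extent: smallest `k` with `P(max null cluster ≥ k) ≤ α`
   under smooth Gaussian null fields (3dClustSim-style, Gaussian ACF).
3. **Hotspot extraction** — each subject's local-maximum voxel (MNI mm)
   within each surviving cluster; cohort sets in *full complement* and
   *one-per-individual* modes.
4. **Topography** — k-means++ clustering of hotspot coordinates with the
   classic two-phase (batch Lloyd + online single-point) update scheme, 1000
   random restarts per k, k scanned 2–10, and the number of clusters chosen
   by maximum mean silhouette; post-hoc Pearson χ² for group and sex balance
   across clusters.
5. **TMS coverage** — Euclidean distances from every hotspot to EEG 10-10
   scalp coordinates and the percentage of hotspots reachable within
   2–5 cm of each electrode, overall and per drug group.

A synthetic cohort generator (coordinate-level spatial mixture and
image-level 4D block-design simulation with planted activation blobs)
provides data with the statistical structure the analysis assumes, so every
stage is testable without access to raw patient data.

The clustering is exposed sklearn-style (`KMeansTopography`,
`SilhouetteKSelector` with `fit`, `labels_`, `cluster_centers_`,
`diagnostics_`), so it composes with scikit-learn tooling; module-level
functions (`kmeans_fit`, `select_k`, …) wrap the estimators.

## Worked example

The default configuration draws a 156-subject cohort (55 cocaine /
48 nicotine / 53 alcohol, 66% responder rate) whose responder hotspots come
from a three-component frontal mixture — medial prefrontal (7, 50, 4),
left lateral prefrontal (−40, 24, 25), right lateral prefrontal
(30, 18, 41) with weights 0.40 / 0.32 / 0.28 and 12 mm dispersion:

```bash
cuetopo run-all --seed 42 --out demo_out
# report written to demo_out/report.json
# subjects=156 responders=104 points=283
```

From `demo_out/report.json` (this exact run):

```
selected k: 3   cluster shares: 40.3% / 30.4% / 29.3%   mean silhouette: 0.53
recovered centroids (mm): (5.2, 49.3, 3.3) (31.7, 18.8, 41.1) (-41.8, 23.4, 26.2)
group x cluster chi2 = 4.84, p = 0.304   sex x cluster chi2 = 4.41, p = 0.110
```

The silhouette scan recovers the three planted components: the selected k is
3, the recovered centroids sit within a few mm of the planted ones, the
medial-prefrontal cluster holds ~40% of the points, and cluster membership
is independent of drug group and sex (non-significant χ²) — the structure
the generator planted. The report also contains a coverage table (best
electrode and percentage of hotspots within 2/3/4/5 cm, for all hotspots and
per drug group), computed against the builtin synthetic 10-10 electrode
table unless you pass `--electrodes your_digitization.csv`.

Other entry points: `cuetopo simulate` (cohort → hotspot TSV),
`cuetopo glm` / `cuetopo hotspots` (NIfTI in, t-maps and hotspot tables
out), `cuetopo cluster` and `cuetopo coverage` (hotspot TSV in). The image
mode of `run-all` (`--mode image`) runs the full 4D simulation → GLM →
correction → extraction path.

## Layout

- `src/cuetopo/volume.py`, `tables.py` — NIfTI/TSV/CSV/JSON io, affine voxel↔mm transforms
- `src/cuetopo/paradigm.py`, `glm.py` — block paradigm, HRF, design matrices, first/second-level GLM
- `src/cuetopo/clusters.py` — labeling, Monte-Carlo extent threshold, mask dilation
- `src/cuetopo/hotspots.py` — hotspot extraction and cohort assembly
- `src/cuetopo/topography.py` — k-means++/two-phase k-means, silhouettes, k selection, χ²
- `src/cuetopo/electrodes.py`, `coverage.py` — 10-10 coordinates, distance/coverage tables
- `src/cuetopo/synthetic.py` — cohort and 4D time-series generators
- `src/cuetopo/config.py`, `pipeline.py`, `cli.py` — configuration, orchestration, CLI

See `docs/methods.md` for the model, parameter defaults, and limitations.
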