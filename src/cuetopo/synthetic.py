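"""Synthetic cohorts with the statistical structure the analysis assumes.

Two levels of simulation:

* coordinate level — per-subject frontal "hotspot" coordinates drawn from a
  three-component isotropic Gaussian spatial mixture (centroids in medial
  prefrontal, left and right lateral prefrontal cortex), with drug-of-choice
  group labels and a responder indicator;
* image level — per-subject 4D block-design BOLD time series with a Gaussian
  activation blob planted at the subject's true locus inside spatially smooth
  Gaussian noise, on a 3 mm frontal grid.

Defaults mirror the cohort structure the pipeline targets: groups of
55/48/53 (cocaine/nicotine/alcohol), a 66% responder rate, mixture centroids
(7,50,4) / (-40,24,25) / (30,18,41) with weights 0.40/0.32/0.28, TR 2.2 s and
8 mm FWHM noise smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hotspots import GROUPS, Hotspot, HotspotSet
from .paradigm import BlockParadigm, build_design
from .volume import MaskVolume, VolumeGrid

__all__ = [
    "MixtureSpec",
    "SubjectTruth",
    "DEFAULT_MIXTURE",
    "DEFAULT_N_PER_GROUP",
    "DEFAULT_RESPONDER_RATE",
    "sample_hotspots",
    "build_cohort",
    "simulate_timeseries",
    "frontal_grid",
]

#: observed per-group male fractions used when assigning synthetic sex labels
_MALE_FRACTION = {"cocaine": 38 / 55, "nicotine": 24 / 48, "alcohol": 39 / 53}

DEFAULT_N_PER_GROUP = {"cocaine": 55, "nicotine": 48, "alcohol": 53}
DEFAULT_RESPONDER_RATE = 103 / 156
#: mean extra hotspots per responder beyond the first (261 points / 103 responders)
DEFAULT_EXTRA_CLUSTER_RATE = 261 / 103 - 1


@dataclass
class MixtureSpec:
    """Isotropic Gaussian spatial mixture of hotspot loci (MNI mm)."""

    centroids: np.ndarray
    weights: np.ndarray
    dispersion_mm: float = 12.0
    group_weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centroids.shape[0] < 1 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must be an (m, 3) array with m >= 1")
        if len(self.weights) != len(self.centroids):
            raise ValueError("weights and centroids length mismatch")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        if self.dispersion_mm < 0:
            raise ValueError("dispersion_mm must be >= 0")

    @property
    def n_components(self) -> int:
        return len(self.weights)


DEFAULT_MIXTURE = MixtureSpec(
    centroids=np.array([[7.0, 50.0, 4.0], [-40.0, 24.0, 25.0], [30.0, 18.0, 41.0]]),
    weights=np.array([0.40, 0.32, 0.28]),
    dispersion_mm=12.0,
)


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    group: str
    responder: bool
    amplitude: float  # percent BOLD signal change; 0 for non-responders
    true_locus: np.ndarray | None = None
    component: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _draw_locus(spec: MixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    comp = int(rng.choice(spec.n_components, p=spec.weights))
    locus = spec.centroids[comp] + rng.normal(0.0, spec.dispersion_mm, size=3)
    return locus, comp


def sample_hotspots(spec: MixtureSpec, n: int, seed: int | None = None,
                    group_labels=None) -> HotspotSet:
    """Draw n hotspot coordinates component-first, then Gaussian around the
    component centroid. Each point keeps its true component label (for
    recovery tests) and gets a drug-group label (uniform over the three
    groups unless ``spec.group_weights`` or explicit labels say otherwise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(spec.n_components, size=n, p=spec.weights)
    coords = spec.centroids[comps] + rng.normal(0.0, spec.dispersion_mm, size=(n, 3))
    if group_labels is None:
        group_labels = [str(g) for g in rng.choice(GROUPS, size=n)]
    points = [
        Hotspot(subject_id=f"s{i:04d}", group=group_labels[i],
                x_mm=float(coords[i, 0]), y_mm=float(coords[i, 1]),
                z_mm=float(coords[i, 2]), peak_t=0.0, cluster_size_voxels=1,
                cluster_rank=1, component=int(comps[i]))
        for i in range(n)
    ]
    return HotspotSet(points=points, mode="full_complement", n_subjects_total=n)


def build_cohort(n_per_group: dict[str, int] | None = None,
                 responder_rate: float = DEFAULT_RESPONDER_RATE,
                 spec: MixtureSpec = DEFAULT_MIXTURE,
                 amplitude: float = 1.0,
                 seed: int | None = None) -> list[SubjectTruth]:
    """One truth record per subject: responders get a mixture-drawn locus and
    the stated amplitude; non-responders get amplitude 0 and no locus."""
    if n_per_group is None:
        n_per_group = dict(DEFAULT_N_PER_GROUP)
    if not 0 <= responder_rate <= 1:
        raise ValueError("responder_rate must be in [0, 1]")
    if any(v < 0 for v in n_per_group.values()):
        raise ValueError("group counts must be >= 0")
    rng = np.random.default_rng(seed)
    cohort: list[SubjectTruth] = []
    i = 0
    for group in GROUPS:
        for _ in range(int(n_per_group.get(group, 0))):
            i += 1
            responder = bool(rng.random() < responder_rate)
            sex = "M" if rng.random() < _MALE_FRACTION[group] else "F"
            if responder:
                locus, comp = _draw_locus(spec, rng)
                cohort.append(SubjectTruth(subject_id=f"sub{i:04d}", group=group,
                                           responder=True, amplitude=amplitude,
                                           true_locus=locus, component=comp, sex=sex))
            else:
                cohort.append(SubjectTruth(subject_id=f"sub{i:04d}", group=group,
                                           responder=False, amplitude=0.0, sex=sex))
    return cohort


def sample_cohort_hotspots(cohort: list[SubjectTruth], spec: MixtureSpec,
                           extra_cluster_rate: float = DEFAULT_EXTRA_CLUSTER_RATE,
                           seed: int | None = None) -> HotspotSet:
    """Coordinate-level fast path: responders contribute ``1 + Poisson(rate)``
    hotspots (rank 1 at the true locus; extras drawn fresh from the mixture),
    non-responders contribute nothing."""
    rng = np.random.default_rng(seed)
    per_subject: list[list[Hotspot]] = []
    for s in cohort:
        hs: list[Hotspot] = []
        if s.responder and s.true_locus is not None:
            n_points = 1 + int(rng.poisson(extra_cluster_rate))
            for rank in range(1, n_points + 1):
                if rank == 1:
                    locus, comp = s.true_locus, s.component
                else:
                    locus, comp = _draw_locus(spec, rng)
                hs.append(Hotspot(subject_id=s.subject_id, group=s.group, sex=s.sex,
                                  x_mm=float(locus[0]), y_mm=float(locus[1]),
                                  z_mm=float(locus[2]), peak_t=0.0,
                                  cluster_size_voxels=1, cluster_rank=rank,
                                  component=comp))
        per_subject.append(hs)
    from .hotspots import assemble_cohort
    return assemble_cohort(per_subject, mode="full_complement",
                           n_subjects_total=len(cohort))


def frontal_grid(voxel_mm: float = 3.0,
                 x_range=(-60.0, 60.0), y_range=(-6.0, 90.0),
                 z_range=(-24.0, 60.0)) -> VolumeGrid:
    """An RAS frontal bounding-box grid at the stated isotropic resolution."""
    shape = tuple(int(round((hi - lo) / voxel_mm)) + 1
                  for lo, hi in (x_range, y_range, z_range))
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = [x_range[0], y_range[0], z_range[0]]
    return VolumeGrid(np.zeros(shape), affine)


def simulate_timeseries(truth: SubjectTruth, paradigm: BlockParadigm,
                        grid: VolumeGrid | None = None, tr_s: float = 2.2,
                        noise_sd: float = 1.0, smoothness_fwhm_mm: float = 8.0,
                        blob_fwhm_mm: float = 14.4, baseline: float = 100.0,
                        seed: int | None = None) -> tuple[np.ndarray, MaskVolume]:
    """Simulate a subject's 4D series: planted blob x HRF-convolved Drug
    regressor, plus spatially smooth Gaussian noise.

    Signal model: ``y(v, t) = baseline * (1 + amplitude/100 * blob(v) * reg(t))
    + noise`` where ``blob`` is a unit-peak Gaussian of ``blob_fwhm_mm`` at the
    true locus and ``reg`` the unit-peak HRF-convolved Drug boxcar. Noise is
    white Gaussian smoothed to ``smoothness_fwhm_mm`` and rescaled back to
    ``noise_sd``. Contrast-to-noise at the blob peak is
    ``baseline * amplitude/100 / noise_sd``.

    The series emulates data that have already been spatially smoothed during
    preprocessing: the noise smoothness default mirrors an 8 mm kernel, and
    the blob default (14.4 mm) is a ~12 mm activation focus observed through
    that kernel (sqrt(12^2 + 8^2)).

    Returns the 4D array (grid shape + time) and an all-ones analysis mask on
    the grid (the grid itself is the frontal analysis box).
    """
    if grid is None:
        grid = frontal_grid()
    n_volumes = int(np.floor(paradigm.total_duration_s / tr_s))
    rng = np.random.default_rng(seed)
    shape = grid.shape
    voxel_sizes = grid.voxel_sizes

    design = build_design(paradigm, tr_s, n_volumes, conditions=["Drug"])
    reg = design.frame["Drug"].to_numpy()
    reg = reg / reg.max()

    blob = np.zeros(shape)
    if truth.responder and truth.amplitude > 0:
        if truth.true_locus is None:
            raise ValueError("responder has no true locus")
        from .volume import mm_to_voxel
        center = mm_to_voxel(grid, truth.true_locus)
        if np.any(center < 0) or np.any(center >= np.asarray(shape)):
            raise ValueError("blob center outside grid")
        sigma_vox = (blob_fwhm_mm / np.sqrt(8 * np.log(2))) / voxel_sizes
        axes = [np.arange(s) for s in shape]
        sq = [((ax - c) / s_v) ** 2 for ax, c, s_v in zip(axes, center, sigma_vox)]
        blob = np.exp(-0.5 * (sq[0][:, None, None] + sq[1][None, :, None]
                              + sq[2][None, None, :]))

    signal = baseline * (1.0 + (truth.amplitude / 100.0)
                         * blob[..., None] * reg[None, None, None, :])
    noise = rng.standard_normal(shape + (n_volumes,))
    if smoothness_fwhm_mm > 0 and noise_sd > 0:
        sigma_vox = (smoothness_fwhm_mm / np.sqrt(8 * np.log(2))) / voxel_sizes
        noise = ndimage.gaussian_filter(noise, sigma=tuple(sigma_vox) + (0.0,))
        noise /= noise.std()
    data = signal + noise_sd * noise
    mask = MaskVolume(VolumeGrid(np.ones(shape), grid.affine))
    return data, mask
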