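"""First- and second-level general linear models for block-design fMRI.

Per-voxel ordinary least squares on the HRF-convolved design; t-maps are
``c'beta / sqrt(sigma2 * c'(X'X)^-1 c)`` with ``df = n_volumes - rank(X)``.
No prewhitening or slice-timing model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .paradigm import DesignMatrix, contrast_vector
from .volume import MaskVolume, StatMap, VolumeGrid

__all__ = ["FirstLevelGLM", "ContrastResult", "fit_first_level", "fit_group_level", "T_SENTINEL"]

#: finite stand-in for an infinite t (zero residual variance); flagged in results
T_SENTINEL = 1e6


@dataclass
class ContrastResult:
    beta: VolumeGrid
    t: StatMap
    residual_variance: VolumeGrid
    df: int
    degenerate_voxels: int = 0


class FirstLevelGLM(BaseEstimator):
    """Per-voxel OLS of a subject's 4D time series on a design matrix.

    Parameters
    ----------
    design : DesignMatrix
        HRF-convolved condition regressors, motion covariates, intercept.
    contrast : dict[str, float]
        Column-name -> weight mapping, e.g. ``{"Drug": 1, "Neutral": -1}``.

    Attributes (after ``fit``)
    --------------------------
    beta_map_ : VolumeGrid          contrast effect size per voxel
    t_map_ : StatMap                t statistic per voxel (masked voxels only)
    sigma2_map_ : VolumeGrid        residual variance per voxel
    df_ : int                       n_volumes - rank(design)
    degenerate_voxels_ : int        voxels where sigma2 == 0 (t set to sentinel)
    """

    def __init__(self, design: DesignMatrix, contrast: dict[str, float]):
        self.design = design
        self.contrast = contrast

    def fit(self, volume4d: np.ndarray, mask: MaskVolume):
        data = np.asarray(volume4d, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4D volume (x, y, z, t)")
        X = self.design.matrix
        n, p = X.shape
        if data.shape[3] != n:
            raise ValueError(f"volume count {data.shape[3]} != design rows {n}")
        if data.shape[:3] != mask.grid.shape:
            raise ValueError("mask/volume shape mismatch")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise ValueError("singular normal equations: design is rank deficient")
        c = contrast_vector(self.design, self.contrast)

        m = mask.bool_array
        Y = data[m].T  # (n_volumes, n_voxels)
        pinv = np.linalg.pinv(X)
        beta = pinv @ Y
        resid = Y - X @ beta
        df = n - rank
        sigma2 = (resid ** 2).sum(axis=0) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        c_var = float(c @ xtx_inv @ c)
        eff = c @ beta
        se = np.sqrt(sigma2 * c_var)
        # zero residual up to roundoff (relative to the per-voxel data scale)
        scale = np.sqrt((Y ** 2).mean(axis=0))
        degenerate = se <= 1e-12 * np.maximum(scale, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(~degenerate, eff / np.where(~degenerate, se, 1.0),
                         np.sign(eff) * T_SENTINEL)

        def into_volume(vals: np.ndarray) -> VolumeGrid:
            out = np.zeros(mask.grid.shape)
            out[m] = vals
            return VolumeGrid(out, mask.grid.affine)

        self.df_ = int(df)
        self.beta_map_ = into_volume(eff)
        self.sigma2_map_ = into_volume(sigma2)
        self.t_map_ = StatMap(into_volume(t), df=self.df_)
        self.degenerate_voxels_ = int(np.sum(degenerate))
        return self

    def result_(self) -> ContrastResult:
        return ContrastResult(beta=self.beta_map_, t=self.t_map_,
                              residual_variance=self.sigma2_map_, df=self.df_,
                              degenerate_voxels=self.degenerate_voxels_)


def fit_first_level(volume4d, design: DesignMatrix, contrast: dict[str, float],
                    mask: MaskVolume) -> ContrastResult:
    """Functional wrapper over :class:`FirstLevelGLM`."""
    return FirstLevelGLM(design, contrast).fit(volume4d, mask).result_()


def fit_group_level(contrast_maps: list[VolumeGrid], mask: MaskVolume | None = None) -> StatMap:
    """One-sample t across subjects' contrast maps (random effects).

    ``df = n - 1``; voxels with zero between-subject variance but nonzero mean
    get the finite sentinel ``T_SENTINEL`` in place of an infinite t.
    """
    if len(contrast_maps) < 2:
        raise ValueError("need >= 2 subjects for a group-level t")
    ref = contrast_maps[0]
    for g in contrast_maps[1:]:
        ref.require_same_grid(g, "contrast map")
    stack = np.stack([g.data for g in contrast_maps], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                     np.where(mean == 0, 0.0, np.sign(mean) * T_SENTINEL))
    if mask is not None:
        t = t * mask.bool_array
    return StatMap(VolumeGrid(t, ref.affine), df=n - 1)
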