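"""Block paradigm reconstruction and HRF-convolved design matrices.

The cue-reactivity task is a 12-minute block design: six 120-second epochs,
each containing alternating 24-second blocks of four conditions (Drug,
Neutral, Blur, Rest), five 4.8-s picture presentations per block. Four 24-s
blocks fill only 96 s of a 120-s epoch; the remaining 24 s are handled by the
``epoch_fill`` policy (see :func:`build_paradigm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "Block",
    "BlockParadigm",
    "DesignMatrix",
    "build_paradigm",
    "hrf",
    "build_design",
    "contrast_vector",
    "CONDITIONS",
]

CONDITIONS = ("Drug", "Neutral", "Blur", "Rest")


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class BlockParadigm:
    """Ordered, non-overlapping condition blocks."""

    blocks: list[Block]
    total_duration_s: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for b in self.blocks:
            if b.duration_s <= 0:
                raise ValueError("block durations must be > 0")
            if b.onset_s < prev_onset:
                raise ValueError("blocks must be ordered by onset")
            if b.onset_s < prev_end - 1e-9:
                raise ValueError("blocks overlap")
            prev_onset, prev_end = b.onset_s, b.onset_s + b.duration_s
        end = max((b.onset_s + b.duration_s for b in self.blocks), default=0.0)
        if abs(self.total_duration_s - end) > 1e-6 and self.total_duration_s < end:
            raise ValueError("total_duration_s shorter than last block end")

    def condition_count(self, condition: str) -> int:
        return sum(1 for b in self.blocks if b.condition == condition)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen


def build_paradigm(
    n_epochs: int = 6,
    block_s: float = 24.0,
    order: Sequence[str] = CONDITIONS,
    epoch_s: float = 120.0,
    epoch_fill: str = "rest_gap",
) -> BlockParadigm:
    """Build the block paradigm.

    With defaults this is the 12-minute task: six 120-s epochs of alternating
    24-s Drug/Neutral/Blur/Rest blocks. Since four 24-s blocks cover only
    96 s of each epoch, ``epoch_fill`` decides the remainder:

    - ``"rest_gap"`` (default): the last 24 s of each epoch are unmodeled
      rest (equivalent to baseline).
    - ``"cycle"``: block slots keep cycling through ``order`` until the epoch
      is full (five slots per 120-s epoch with defaults).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if block_s <= 0:
        raise ValueError("block_s must be > 0")
    if epoch_fill not in ("rest_gap", "cycle"):
        raise ValueError(f"unknown epoch_fill {epoch_fill!r}")
    n_slots_exact = epoch_s / block_s
    if epoch_fill == "cycle" and abs(n_slots_exact - round(n_slots_exact)) > 1e-9:
        raise ValueError("epoch_s must be a multiple of block_s for epoch_fill='cycle'")
    if len(order) * block_s > epoch_s + 1e-9:
        raise ValueError("ordered blocks do not fit in one epoch")

    blocks: list[Block] = []
    for e in range(n_epochs):
        t0 = e * epoch_s
        if epoch_fill == "rest_gap":
            for i, cond in enumerate(order):
                blocks.append(Block(cond, t0 + i * block_s, block_s))
        else:
            n_slots = int(round(n_slots_exact))
            for i in range(n_slots):
                blocks.append(Block(order[i % len(order)], t0 + i * block_s, block_s))
    return BlockParadigm(blocks=blocks, total_duration_s=n_epochs * epoch_s)


def hrf(t_s, peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
        ratio: float = 6.0, dispersion_s: float = 1.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, scaled to unit peak.

    ``h(t) = g(t; peak) - g(t; undershoot)/ratio`` with gamma-pdf lobes of the
    stated delays and dispersion; ``h(0) = 0`` and the peak sits near 5 s.
    """
    t = np.asarray(t_s, dtype=float)
    pos = _stats.gamma.pdf(t, peak_delay_s / dispersion_s, scale=dispersion_s)
    neg = _stats.gamma.pdf(t, undershoot_delay_s / dispersion_s, scale=dispersion_s)
    h = pos - neg / ratio
    h = np.where(t < 0, 0.0, h)
    # unit-peak scaling on a dense reference grid so scalar calls are stable
    ref = np.arange(0, 48.0, 0.01)
    refh = (_stats.gamma.pdf(ref, peak_delay_s / dispersion_s, scale=dispersion_s)
            - _stats.gamma.pdf(ref, undershoot_delay_s / dispersion_s, scale=dispersion_s) / ratio)
    return h / refh.max()


@dataclass
class DesignMatrix:
    """Named design matrix sampled at volume acquisition times ``t = i*TR``."""

    frame: pd.DataFrame
    tr_s: float
    condition_names: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def _convolved_regressor(paradigm: BlockParadigm, condition: str, tr_s: float,
                         n_volumes: int, dt: float = 0.1) -> np.ndarray:
    n_fine = int(np.ceil(max(paradigm.total_duration_s, n_volumes * tr_s) / dt)) + 1
    boxcar = np.zeros(n_fine)
    tgrid = np.arange(n_fine) * dt
    for b in paradigm.blocks:
        if b.condition == condition:
            boxcar[(tgrid >= b.onset_s) & (tgrid < b.onset_s + b.duration_s)] = 1.0
    kernel = hrf(np.arange(0, 32.0, dt))
    conv = np.convolve(boxcar, kernel)[:n_fine] * dt
    sample_idx = np.rint(np.arange(n_volumes) * tr_s / dt).astype(int)
    return conv[sample_idx]


def build_design(
    paradigm: BlockParadigm,
    tr_s: float,
    n_volumes: int,
    motion: np.ndarray | None = None,
    conditions: Sequence[str] | None = None,
    drop_zero_columns: bool = True,
) -> DesignMatrix:
    """HRF-convolved condition regressors + 6 motion covariates + intercept.

    Rest is the implicit baseline and is never modeled. All-zero motion
    columns are dropped (recorded in ``dropped_columns``) so the design stays
    full rank; a rank-deficient design raises ``ValueError``.
    """
    if conditions is None:
        conditions = [c for c in paradigm.conditions() if c != "Rest"]
    cols: dict[str, np.ndarray] = {}
    for cond in conditions:
        reg = _convolved_regressor(paradigm, cond, tr_s, n_volumes)
        if np.allclose(reg, 0):
            raise ValueError(f"condition {cond!r} has an all-zero regressor")
        cols[cond] = reg

    dropped: list[str] = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape == (n_volumes, 6):
            motion = motion.T
        if motion.shape != (6, n_volumes):
            raise ValueError("motion must be 6 x n_volumes")
        if not np.all(np.isfinite(motion)):
            raise ValueError("motion covariates must be finite")
        names = ("mot_x", "mot_y", "mot_z", "mot_yaw", "mot_pitch", "mot_roll")
        for name, row in zip(names, motion):
            if drop_zero_columns and np.allclose(row, 0):
                dropped.append(name)
            else:
                cols[name] = row
    cols["intercept"] = np.ones(n_volumes)

    frame = pd.DataFrame(cols)
    design = DesignMatrix(frame=frame, tr_s=tr_s,
                          condition_names=tuple(conditions),
                          dropped_columns=tuple(dropped))
    if design.rank < frame.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return design


def contrast_vector(design: DesignMatrix, weights: dict[str, float]) -> np.ndarray:
    """Expand a ``{column: weight}`` mapping into a contrast vector."""
    unknown = set(weights) - set(design.columns)
    if unknown:
        raise ValueError(f"unknown contrast columns: {sorted(unknown)}")
    return np.array([weights.get(c, 0.0) for c in design.columns], dtype=float)
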