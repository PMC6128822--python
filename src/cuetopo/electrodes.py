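"""EEG 10-10 / 10-5 electrode coordinates in MNI millimeters.

The builtin default table is a *synthetic* digitization: it is computed from
the standard fractional-arc placement rules of the 10-10 system (midline
nasion-to-inion arc at 10% steps; a circumferential ring at the 10% level;
coronal arcs from ring to midline) laid out on an ellipsoidal scalp model
whose center and semi-axes approximate the MNI template head. It is intended
for method development and testing; analyses of real data should pass a CSV
of digitized coordinates (columns ``label,x,y,z`` in MNI mm) to
:func:`load_electrodes`, which records the file as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ElectrodeSet", "load_electrodes", "builtin_1010"]

#: labels the coverage analysis must be able to resolve
REQUIRED_LABELS = {"FPz", "FP1", "FP2", "AF3", "AF7", "F5", "AF5"}

# ellipsoidal scalp model (synthetic; see module docstring): center and
# semi-axes in mm fitted so the vertex lands near (0,-14,95), the 10%
# circumferential ring near the z = -5 plane (frontal pole ~(0,88,-5),
# temporal points ~(+/-84,-14,-5), occipital pole ~(0,-115,-5)), matching
# plausible MNI scalp geometry
_CENTER = np.array([0.0, -13.5, -49.7])
_SEMI_AXES = np.array([88.3, 106.7, 144.7])

# per-row azimuth of the outer (ring) electrode, degrees from the midline
_ROWS = {
    # row prefix: (midline fraction f along Nz->Iz arc, ring azimuth deg,
    #              lateral labels as (label_stem fraction) pairs)
    "FP": (0.1, 18.0, {}),
    "AF": (0.2, 36.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "F": (0.3, 54.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "FC": (0.4, 72.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "C": (0.5, 90.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "CP": (0.6, 108.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "P": (0.7, 126.0, {"1": 0.25, "3": 0.5, "5": 0.75}),
    "PO": (0.8, 144.0, {"3": 0.5}),
    "O": (0.9, 162.0, {}),
}
_MIDLINE = {"FP": "FPz", "AF": "AFz", "F": "Fz", "FC": "FCz", "C": "Cz",
            "CP": "CPz", "P": "Pz", "PO": "POz", "O": "Oz"}
# ring electrode names (left, right) per row
_RING = {"FP": ("FP1", "FP2"), "AF": ("AF7", "AF8"), "F": ("F7", "F8"),
         "FC": ("FT7", "FT8"), "C": ("T7", "T8"), "CP": ("TP7", "TP8"),
         "P": ("P7", "P8"), "PO": ("PO7", "PO8"), "O": ("O1", "O2")}


def _unit_midline(f: float) -> np.ndarray:
    """Unit-sphere point at fraction f of the front-to-back sagittal arc."""
    gamma = np.deg2rad(180.0 * f)
    return np.array([0.0, np.cos(gamma), np.sin(gamma)])


def _unit_ring(azimuth_deg: float, side: int) -> np.ndarray:
    """Unit-sphere point on the 10%-elevation circumferential ring.

    ``side`` +1 = right (positive x), -1 = left."""
    beta = np.deg2rad(azimuth_deg)
    elev = np.deg2rad(18.0)
    return np.array([side * np.sin(beta) * np.cos(elev),
                     np.cos(beta) * np.cos(elev),
                     np.sin(elev)])


def _slerp(u: np.ndarray, v: np.ndarray, g: float) -> np.ndarray:
    omega = np.arccos(np.clip(u @ v, -1.0, 1.0))
    if omega < 1e-12:
        return u
    return (np.sin((1 - g) * omega) * u + np.sin(g * omega) * v) / np.sin(omega)


def _to_mni(unit: np.ndarray) -> np.ndarray:
    return _CENTER + _SEMI_AXES * unit


def builtin_1010() -> pd.DataFrame:
    """Synthetic 10-10 (+10-5 intermediate) MNI coordinate table.

    Columns ``label,x,y,z``; computed, not digitized — see module docstring.
    """
    rows: list[dict] = []

    def add(label: str, unit: np.ndarray) -> None:
        x, y, z = _to_mni(unit)
        rows.append({"label": label, "x": round(float(x), 2),
                     "y": round(float(y), 2), "z": round(float(z), 2)})

    for prefix, (f, az, laterals) in _ROWS.items():
        mid = _unit_midline(f)
        add(_MIDLINE[prefix], mid)
        for side, ring_label in zip((-1, 1), _RING[prefix]):
            ring = _unit_ring(az, side)
            add(ring_label, ring)
            for stem, frac in laterals.items():
                num = int(stem) if side < 0 else int(stem) + 1
                add(f"{prefix}{num}", _slerp(mid, ring, frac))
    return pd.DataFrame(rows)


@dataclass
class ElectrodeSet:
    """Labeled scalp electrode positions (MNI mm) with provenance."""

    entries: pd.DataFrame  # columns: label, x, y, z
    provenance: str

    def __post_init__(self) -> None:
        required_cols = {"label", "x", "y", "z"}
        if not required_cols.issubset(self.entries.columns):
            raise ValueError(f"electrode table needs columns {sorted(required_cols)}")
        labels = self.entries["label"]
        if labels.duplicated().any():
            dupes = sorted(labels[labels.duplicated()].unique())
            raise ValueError(f"duplicate electrode labels: {dupes}")
        xyz = self.entries[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("electrode positions must be finite")

    @property
    def labels(self) -> list[str]:
        return list(self.entries["label"])

    @property
    def positions(self) -> np.ndarray:
        return self.entries[["x", "y", "z"]].to_numpy(dtype=float)

    def position(self, label: str) -> np.ndarray:
        row = self.entries[self.entries["label"] == label]
        if row.empty:
            raise KeyError(f"no electrode {label!r}")
        return row[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def load_electrodes(source="builtin", strict: bool = False) -> ElectrodeSet:
    """Load electrode coordinates from a CSV path or the builtin table.

    ``strict=True`` additionally requires every label used in the coverage
    report (FPz, FP1, FP2, AF3, AF5, AF7, F5) to be present.
    """
    if isinstance(source, (str, Path)) and str(source) == "builtin":
        es = ElectrodeSet(entries=builtin_1010(),
                          provenance="builtin synthetic ellipsoidal-scalp 10-10/10-5 digitization")
    else:
        frame = pd.read_csv(source)
        es = ElectrodeSet(entries=frame, provenance=str(source))
    if strict:
        missing = REQUIRED_LABELS - set(es.labels)
        if missing:
            raise ValueError(f"electrode table missing required labels: {sorted(missing)}")
    return es
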