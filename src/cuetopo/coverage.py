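"""Hotspot-to-electrode distances and TMS coverage at fixed radii.

For each scalp electrode and each radius r (2-5 cm by default) the coverage
is the percentage of hotspots whose straight-line (Euclidean, 3D mm) distance
to that electrode is at most r. The "best" electrode at a radius is the one
covering the most hotspots; ties (after rounding percentages to the printed
precision) are reported jointly, e.g. "FPz/FP2".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .electrodes import ElectrodeSet
from .hotspots import GROUPS, HotspotSet

__all__ = [
    "CoverageTable",
    "hotspot_electrode_distances",
    "coverage_at_radii",
    "subgroup_coverage",
    "format_coverage_report",
    "DEFAULT_RADII_MM",
]

DEFAULT_RADII_MM = (20.0, 30.0, 40.0, 50.0)


def hotspot_electrode_distances(hotspot_set: HotspotSet,
                                electrodes: ElectrodeSet) -> pd.DataFrame:
    """Rectangular distance matrix (hotspots x electrodes) in mm."""
    if len(hotspot_set) == 0:
        raise ValueError("empty hotspot set")
    if len(electrodes.labels) == 0:
        raise ValueError("empty electrode set")
    D = cdist(hotspot_set.coords, electrodes.positions)
    return pd.DataFrame(D, columns=electrodes.labels)


@dataclass
class CoverageTable:
    """Per-electrode coverage percentages at each radius, plus best electrodes."""

    radii_mm: tuple[float, ...]
    coverage: pd.DataFrame          # electrodes (rows) x radii (cols), percent
    best: dict[float, list[str]]    # radius -> jointly best electrode labels
    n_hotspots: int
    rounding: str = "integer"

    def best_label(self, radius: float) -> str:
        return "/".join(self.best[radius])


def coverage_at_radii(distances: pd.DataFrame,
                      radii_mm=DEFAULT_RADII_MM,
                      rounding: str = "integer") -> CoverageTable:
    """Coverage percentages per electrode per radius, with joint best labels.

    ``rounding="integer"`` compares integer-rounded percentages when declaring
    ties (matching reports that print whole percents); ``"exact"`` compares
    raw counts.
    """
    radii = tuple(float(r) for r in radii_mm)
    if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
        raise ValueError("radii must be positive and sorted ascending")
    if rounding not in ("integer", "exact"):
        raise ValueError("rounding must be 'integer' or 'exact'")
    n = len(distances)
    if n == 0:
        raise ValueError("empty hotspot set")
    D = distances.to_numpy(dtype=float)
    cov = {}
    for r in radii:
        cov[r] = 100.0 * (D <= r).sum(axis=0) / n
    frame = pd.DataFrame(cov, index=list(distances.columns))
    frame.index.name = "electrode"
    best: dict[float, list[str]] = {}
    for r in radii:
        vals = frame[r].to_numpy()
        key = np.rint(vals).astype(int) if rounding == "integer" else vals
        top = key.max()
        best[r] = [lab for lab, v in zip(frame.index, key) if v == top]
    return CoverageTable(radii_mm=radii, coverage=frame, best=best,
                         n_hotspots=n, rounding=rounding)


def subgroup_coverage(hotspot_set: HotspotSet, electrodes: ElectrodeSet,
                      radii_mm=DEFAULT_RADII_MM,
                      rounding: str = "integer") -> dict[str, CoverageTable]:
    """Coverage for the full set ("all") and per drug-of-choice subgroup.

    Empty subgroups are omitted (reported as missing rows, not failures).
    """
    out: dict[str, CoverageTable] = {}
    out["all"] = coverage_at_radii(
        hotspot_electrode_distances(hotspot_set, electrodes), radii_mm, rounding)
    for group in GROUPS:
        sub = hotspot_set.subset_by_group(group)
        if len(sub) == 0:
            continue
        out[group] = coverage_at_radii(
            hotspot_electrode_distances(sub, electrodes), radii_mm, rounding)
    return out


def format_coverage_report(tables: dict[str, CoverageTable]) -> pd.DataFrame:
    """Best-electrode summary: one row per cohort/subgroup, one column per
    radius, cells like ``"49% FPz"`` (joint winners slash-separated)."""
    rows = []
    for name, tab in tables.items():
        row: dict[str, object] = {"hotspots": name, "n": tab.n_hotspots}
        for r in tab.radii_mm:
            pct = tab.coverage.loc[tab.best[r][0], r]
            pct_txt = f"{pct:.0f}%" if tab.rounding == "integer" else f"{pct:.1f}%"
            row[f"{r / 10:g} cm"] = f"{pct_txt} {tab.best_label(r)}"
        rows.append(row)
    return pd.DataFrame(rows)
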