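"""Hotspot extraction: reduce corrected per-subject maps to peak coordinates.

A *hotspot* is the local-maximum voxel (in MNI mm) within a surviving
activation cluster; the rank-1 hotspot sits in the subject's most significant
cluster. Cohort-level sets come in two modes: ``full_complement`` (every
surviving cluster of every subject) and ``one_per_individual`` (rank-1 only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clusters import ClusterRecord
from .tables import read_table, write_table
from .volume import MaskVolume, StatMap, voxel_to_mm

__all__ = ["Hotspot", "HotspotSet", "rank_clusters", "extract_hotspots", "assemble_cohort"]

GROUPS = ("cocaine", "alcohol", "nicotine")


@dataclass
class Hotspot:
    subject_id: str
    group: str
    x_mm: float
    y_mm: float
    z_mm: float
    peak_t: float
    cluster_size_voxels: int
    cluster_rank: int
    sex: str | None = None
    component: int | None = None  # planted mixture component (synthetic truth)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.cluster_rank < 1:
            raise ValueError("cluster_rank must be >= 1")

    @property
    def mm(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.z_mm])


@dataclass
class HotspotSet:
    """A cohort-level collection of hotspots."""

    points: list[Hotspot]
    mode: str  # {"full_complement", "one_per_individual"}
    n_subjects_total: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("full_complement", "one_per_individual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "one_per_individual":
            ids = [p.subject_id for p in self.points]
            if len(set(ids)) != len(ids):
                raise ValueError("one_per_individual mode requires unique subject ids")
            if any(p.cluster_rank != 1 for p in self.points):
                raise ValueError("one_per_individual mode requires cluster_rank 1 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        return np.array([p.mm for p in self.points]).reshape(len(self.points), 3)

    @property
    def groups(self) -> np.ndarray:
        return np.array([p.group for p in self.points])

    @property
    def responder_ids(self) -> list[str]:
        return sorted({p.subject_id for p in self.points})

    @property
    def responder_count(self) -> int:
        return len(self.responder_ids)

    @property
    def responder_fraction(self) -> float | None:
        if self.n_subjects_total is None:
            return None
        if self.n_subjects_total == 0:
            return 0.0
        return self.responder_count / self.n_subjects_total

    def restricted(self) -> "HotspotSet":
        """The one-cluster-per-individual subset (rank-1 points only)."""
        return HotspotSet(points=[p for p in self.points if p.cluster_rank == 1],
                          mode="one_per_individual",
                          n_subjects_total=self.n_subjects_total)

    def subset_by_group(self, group: str) -> "HotspotSet":
        return HotspotSet(points=[p for p in self.points if p.group == group],
                          mode=self.mode)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dict(asdict(p), mode=self.mode) for p in self.points]
        cols = ["subject_id", "group", "x_mm", "y_mm", "z_mm", "peak_t",
                "cluster_size_voxels", "cluster_rank", "sex", "component", "mode"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path) -> None:
        write_table(self.to_dataframe(), path, dialect="TSV")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       n_subjects_total: int | None = None) -> "HotspotSet":
        mode = frame["mode"].iloc[0] if "mode" in frame and len(frame) else "full_complement"
        points = []
        for _, r in frame.iterrows():
            sex = r.get("sex")
            comp = r.get("component")
            points.append(Hotspot(
                subject_id=str(r["subject_id"]), group=str(r["group"]),
                x_mm=float(r["x_mm"]), y_mm=float(r["y_mm"]), z_mm=float(r["z_mm"]),
                peak_t=float(r.get("peak_t", 0.0)),
                cluster_size_voxels=int(r.get("cluster_size_voxels", 1)),
                cluster_rank=int(r.get("cluster_rank", 1)),
                sex=None if pd.isna(sex) else str(sex),
                component=None if comp is None or pd.isna(comp) else int(comp),
            ))
        return cls(points=points, mode=mode, n_subjects_total=n_subjects_total)

    @classmethod
    def from_tsv(cls, path, n_subjects_total: int | None = None) -> "HotspotSet":
        return cls.from_dataframe(read_table(path, "TSV"), n_subjects_total)


def rank_clusters(clusters: list[ClusterRecord]) -> list[ClusterRecord]:
    """Order clusters by significance: ascending cluster-level p when present
    (equivalently descending extent under a shared null), ties broken by
    descending peak t, then lexicographic peak index. Sets ``rank`` in place.
    """
    def key(c: ClusterRecord):
        p = c.cluster_p if c.cluster_p is not None else -c.size_voxels
        return (p, -c.size_voxels, -c.peak_t, c.peak_voxel_index)

    ordered = sorted(clusters, key=key)
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def extract_hotspots(map: StatMap, clusters: list[ClusterRecord], mask: MaskVolume,
                     subject_id: str, group: str, sex: str | None = None,
                     max_per_subject: int | None = None) -> list[Hotspot]:
    """One hotspot per retained cluster: the member voxel with maximal t.

    ``clusters`` must already be ranked (see :func:`rank_clusters`). Subjects
    with no surviving clusters simply contribute an empty list.
    """
    map.grid.require_same_grid(mask.grid, "mask")
    m = mask.bool_array
    out: list[Hotspot] = []
    for c in clusters:
        if max_per_subject is not None and len(out) >= max_per_subject:
            break
        members = c.member_voxel_indices
        inside = m[tuple(members.T)]
        if not inside.any():
            raise ValueError(f"cluster {c.label_id} has no in-mask member")
        members = members[inside]
        tvals = map.grid.data[tuple(members.T)]
        order = np.lexsort((members[:, 2], members[:, 1], members[:, 0], -tvals))
        peak = members[order[0]]
        mm = voxel_to_mm(map.grid, peak)
        out.append(Hotspot(
            subject_id=subject_id, group=group, sex=sex,
            x_mm=float(mm[0]), y_mm=float(mm[1]), z_mm=float(mm[2]),
            peak_t=float(tvals.max()), cluster_size_voxels=int(c.size_voxels),
            cluster_rank=int(c.rank if c.rank is not None else len(out) + 1),
        ))
    return out


def assemble_cohort(per_subject_hotspots: Mapping[str, Iterable[Hotspot]] | Iterable[Iterable[Hotspot]],
                    mode: str = "full_complement",
                    n_subjects_total: int | None = None) -> HotspotSet:
    """Concatenate per-subject hotspots into a cohort set.

    ``full_complement`` keeps every hotspot; ``one_per_individual`` keeps only
    each subject's rank-1 hotspot. Duplicate (subject, rank) pairs raise.
    """
    if isinstance(per_subject_hotspots, Mapping):
        lists = list(per_subject_hotspots.values())
    else:
        lists = [list(v) for v in per_subject_hotspots]
    seen: set[tuple[str, int]] = set()
    points: list[Hotspot] = []
    for hs in lists:
        for h in hs:
            key = (h.subject_id, h.cluster_rank)
            if key in seen:
                raise ValueError(f"duplicate (subject, cluster_rank) pair {key}")
            seen.add(key)
            points.append(h)
    if mode == "one_per_individual":
        points = [p for p in points if p.cluster_rank == 1]
    if n_subjects_total is None:
        n_subjects_total = len(lists)
    return HotspotSet(points=points, mode=mode, n_subjects_total=n_subjects_total)
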