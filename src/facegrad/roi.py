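"""Face-selective ROI definition and vein-voxel exclusion.

An ROI is the largest connected set of voxels inside an anatomical search
zone whose localizer contrast (faces > objects) is significant at an
uncorrected threshold (p < 0.01 by default).  Because large draining
veins inflate BOLD amplitudes far beyond neural signal at high field,
voxels whose percent signal change to faces exceeds 4% are excluded
before any pattern analysis.

Connectivity is taken from the patch/volume adjacency structure (4-neighbor
in 2-D grids, 6-neighbor in 3-D volumes), the most conservative standard
choice for "continuous voxels".
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import EmptyROIError, InsufficientDataError, ROINotFoundError
from .glm import BetaMap

__all__ = ["ROI", "localizer_contrast", "define_roi", "exclude_veins"]


@dataclass
class ROI:
    """A named set of voxel ids restricted to an anatomical zone."""

    name: str
    voxel_ids: np.ndarray
    zone: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.zone = np.asarray(self.zone)
        if self.voxel_ids.size == 0:
            raise EmptyROIError(f"ROI {self.name!r} has no voxels")
        if not set(self.voxel_ids.tolist()) <= set(self.zone.tolist()):
            raise ValueError("ROI voxels must lie inside the anatomical zone")

    def __len__(self) -> int:
        return int(self.voxel_ids.size)

    def manifest(self) -> dict:
        return {"name": self.name, "n_voxels": len(self),
                "voxel_ids": [int(v) for v in self.voxel_ids]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def localizer_contrast(
    betas_by_run: Sequence[BetaMap], cond_a: str, cond_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel one-sided paired t (cond_a > cond_b) across runs.

    Returns (t, p) aligned with the voxel ids of the first run's BetaMap.
    Voxels whose run-to-run differences are constant have an undefined t
    and get NaN (they are dropped by thresholding) — except the exact
    identity case where every difference is zero, which is reported as
    t = 0, p = 0.5 (no evidence either way).
    """
    if len(betas_by_run) < 2:
        raise InsufficientDataError("paired t across runs needs at least 2 runs")
    vox = betas_by_run[0].voxel_ids
    for bm in betas_by_run[1:]:
        if not np.array_equal(bm.voxel_ids, vox):
            raise ValueError("all runs must share the same voxel set")
    diffs = np.stack([bm.get(cond_a) - bm.get(cond_b) for bm in betas_by_run])
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.full(vox.shape[0], np.nan)
    p = np.full(vox.shape[0], np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = sp_stats.t.sf(t[ok], df=n - 1)  # one-sided, a > b
    all_zero = ~ok & (mean == 0)
    t[all_zero] = 0.0
    p[all_zero] = 0.5
    return t, p


def _components(ids: np.ndarray, adjacency: Mapping[int, Sequence[int]]) -> list[list[int]]:
    """Connected components of the subgraph induced by ``ids`` (BFS)."""
    members = set(int(v) for v in ids)
    seen: set[int] = set()
    comps = []
    for start in ids:
        start = int(start)
        if start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.append(v)
            for nb in adjacency.get(v, ()):
                nb = int(nb)
                if nb in members and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def define_roi(
    voxel_ids: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    adjacency: Mapping[int, Sequence[int]],
    p_threshold: float = 0.01,
    zone: np.ndarray | None = None,
    name: str = "roi",
) -> ROI:
    """Threshold, extract connected components, keep the largest.

    ``zone`` restricts the search to an anatomical mask (voxel id set);
    by default all given voxels are searched.  NaN p-values never pass the
    threshold.  Size ties between components resolve to the one with the
    larger peak t (deterministic).  Raises :class:`ROINotFoundError` when
    no voxel passes — some subjects simply lack a localizable ROI.
    """
    voxel_ids = np.asarray(voxel_ids)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if zone is None:
        zone = voxel_ids
    zone_set = set(int(v) for v in np.asarray(zone).tolist())
    if not zone_set:
        raise ValueError("anatomical zone is empty")
    with np.errstate(invalid="ignore"):
        passing = (p < p_threshold) & np.isfinite(p)
    sel = [int(v) for v, ok in zip(voxel_ids, passing) if ok and int(v) in zone_set]
    if not sel:
        raise ROINotFoundError(
            f"no voxel with p < {p_threshold} inside the zone for {name!r}"
        )
    tmap = {int(v): float(tv) for v, tv in zip(voxel_ids, t)}
    comps = _components(np.asarray(sel), adjacency)
    best = max(comps, key=lambda c: (len(c), max(tmap[v] for v in c)))
    order = {int(v): i for i, v in enumerate(voxel_ids)}
    best_sorted = sorted(best, key=lambda v: order[v])
    return ROI(name=name, voxel_ids=np.asarray(best_sorted), zone=np.asarray(sorted(zone_set)))


def exclude_veins(
    roi: ROI,
    psc_face: np.ndarray | Mapping[int, float],
    threshold_pct: float = 4.0,
) -> ROI:
    """Drop vein-contaminated voxels: face-condition PSC strictly above threshold.

    A voxel at exactly the threshold is retained ("larger than" is strict).
    ``psc_face`` is either an array aligned with ``roi.voxel_ids`` or a
    {voxel_id: psc} mapping; it must cover every ROI voxel.  Raises
    :class:`EmptyROIError` if nothing survives.
    """
    if isinstance(psc_face, Mapping):
        try:
            psc = np.array([float(psc_face[int(v)]) for v in roi.voxel_ids])
        except KeyError as e:
            raise ValueError(f"PSC undefined for ROI voxel {e}") from None
    else:
        psc = np.asarray(psc_face, dtype=float)
        if psc.shape[0] != len(roi):
            raise ValueError("psc_face must align with roi.voxel_ids")
    if np.any(~np.isfinite(psc)):
        raise ValueError("PSC must be finite for all ROI voxels")
    keep = psc <= threshold_pct
    if not np.any(keep):
        raise EmptyROIError(
            f"vein exclusion at {threshold_pct}% removed every voxel of {roi.name!r}"
        )
    return ROI(name=roi.name, voxel_ids=roi.voxel_ids[keep], zone=roi.zone)
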