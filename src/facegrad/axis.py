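"""Projection of voxel/vertex responses onto an anatomical axis.

The axis is an ordered polyline drawn along an anatomical landmark (the
mid-fusiform sulcus for the FFA, the occipitotemporal/inferior occipital
sulcus for the OFA), oriented posterior -> anterior so that arc-length
position 0 is the posterior end.  Each vertex is assigned the arc-length
position of its nearest point on the polyline (its orthogonal projection,
clamped to the endpoints) and the Euclidean distance to that point.
Profiles are fixed-width bins of projected positions; the gradient
statistic is the Pearson correlation between a response contrast
(e.g. eyes - mouth) and position, so a negative r means a posterior bias
of the first condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import ZeroVarianceError

__all__ = [
    "AnatomicalAxis",
    "SpatialProfile",
    "project_to_axis",
    "build_profile",
    "gradient_correlation",
]


@dataclass
class AnatomicalAxis:
    """Ordered polyline in mm; the first point is the posterior end."""

    polyline: np.ndarray
    posterior_to_anterior: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.polyline, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("polyline needs at least two points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline coordinates must be finite")
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        if np.any(seg_len == 0):
            raise ValueError("consecutive polyline points must be distinct")
        self.polyline = pts
        self._seg = seg
        self._seg_len = seg_len
        # cumulative arc length at each polyline point, strictly increasing
        self.arc = np.concatenate([[0.0], np.cumsum(seg_len)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    @property
    def ndim(self) -> int:
        return self.polyline.shape[1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "polyline_mm": self.polyline.tolist(),
                    "posterior_to_anterior": self.posterior_to_anterior,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "AnatomicalAxis":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["polyline_mm"], dtype=float),
                   d.get("posterior_to_anterior", True))


def project_to_axis(
    coords: np.ndarray, axis: AnatomicalAxis
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the polyline: (arc-length position mm, distance mm).

    The projection onto each segment is clamped to the segment, so points
    past the anterior endpoint take position = total length; ties between
    equidistant segments resolve to the smaller arc-length position.
    Empty input returns empty arrays.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0:
        return np.empty(0), np.empty(0)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != axis.ndim:
        raise ValueError(
            f"points are {pts.shape[1]}-D but axis is {axis.ndim}-D"
        )
    n = pts.shape[0]
    best_d2 = np.full(n, np.inf)
    best_pos = np.zeros(n)
    starts = axis.polyline[:-1]
    for i in range(len(starts)):
        a = starts[i]
        v = axis._seg[i]
        L = axis._seg_len[i]
        # parametric foot of perpendicular, clamped to the segment
        t = np.clip((pts - a) @ v / (L * L), 0.0, 1.0)
        foot = a + t[:, None] * v
        d2 = np.einsum("ij,ij->i", pts - foot, pts - foot)
        # strict < keeps the earlier (smaller arc-length) segment on exact ties
        better = d2 < best_d2 - 1e-12 * (1.0 + d2)
        best_d2[better] = d2[better]
        best_pos[better] = axis.arc[i] + t[better] * L
    return best_pos, np.sqrt(best_d2)


@dataclass
class SpatialProfile:
    """Binned 1-D response profile along the axis, per condition."""

    bin_centers: np.ndarray
    mean: dict[str, np.ndarray] = field(default_factory=dict)
    sem: dict[str, np.ndarray] = field(default_factory=dict)
    n_per_bin: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    bin_width: float = 1.2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.mean:
            for i, c in enumerate(self.bin_centers):
                rows.append(
                    {
                        "bin_center_mm": c,
                        "condition": cond,
                        "mean": self.mean[cond][i],
                        "sem": self.sem[cond][i],
                        "n": int(self.n_per_bin[i]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_profile(
    positions: np.ndarray,
    values: np.ndarray | dict[str, np.ndarray],
    bin_width: float = 1.2,
) -> SpatialProfile:
    """Bin projected positions into fixed-width bins from 0 and average responses.

    ``values`` may be a single array or a {condition: array} mapping sharing
    one set of positions.  Bins with no vertex are omitted.  SEM uses the
    n-1 convention and is 0 for singleton bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = np.asarray(positions, dtype=float)
    if isinstance(values, dict):
        val_map = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    else:
        val_map = {"response": np.asarray(values, dtype=float)}
    for k, v in val_map.items():
        if v.shape != pos.shape:
            raise ValueError(f"values[{k!r}] length differs from positions")
    if pos.size == 0:
        return SpatialProfile(np.empty(0), {}, {}, np.empty(0, dtype=int), bin_width)
    n_bins = max(1, int(np.floor(pos.max() / bin_width)) + 1)
    idx = np.minimum((pos / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    centers = (np.arange(n_bins) + 0.5) * bin_width
    mean, sem = {}, {}
    for cond, v in val_map.items():
        s = np.bincount(idx, weights=v, minlength=n_bins)
        m = np.divide(s, counts, out=np.zeros(n_bins), where=keep)
        ss = np.bincount(idx, weights=v * v, minlength=n_bins)
        var = np.zeros(n_bins)
        multi = counts > 1
        var[multi] = (ss[multi] - counts[multi] * m[multi] ** 2) / (counts[multi] - 1)
        var = np.clip(var, 0, None)
        mean[cond] = m[keep]
        sem[cond] = np.sqrt(var[keep] / counts[keep])
    return SpatialProfile(
        bin_centers=centers[keep],
        mean=mean,
        sem=sem,
        n_per_bin=counts[keep],
        bin_width=bin_width,
    )


def gradient_correlation(
    positions: np.ndarray, diff_values: np.ndarray
) -> float:
    """Pearson r between a response contrast and posterior->anterior position.

    Computed across individual vertices (not bins); a negative r means the
    first condition of the contrast is biased toward the posterior end.
    """
    pos = np.asarray(positions, dtype=float)
    diff = np.asarray(diff_values, dtype=float)
    if pos.shape != diff.shape:
        raise ValueError("positions and diff_values must have the same length")
    if pos.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(pos) == 0 or np.ptp(diff) == 0:
        raise ZeroVarianceError("constant input to gradient correlation")
    r, _ = sp_stats.pearsonr(pos, diff)
    return float(r)
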