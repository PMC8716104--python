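"""Synthetic cortical patches, beta patterns, and time series with known truth.

Every downstream stage of the pipeline is exercised on data generated
here, where the spatial organization is planted and therefore known:

* a regular grid "patch" stands in for a flattened piece of cortical
  surface (1.2 mm vertex pitch by default, matching high-field voxels);
* per-voxel condition responses are a shared baseline pattern plus a
  condition-specific linear gradient along an anatomical axis plus
  i.i.d. Gaussian noise — the structure implied by a general intrinsic
  sensitivity profile overlaid with part-specific posterior/anterior
  biases;
* a subset of voxels is made vein-like by inflating their amplitudes
  above the 4% percent-signal-change exclusion threshold;
* block-design BOLD series are the design matrix times the planted betas
  plus noise (optionally AR(1)), so GLM estimates can be checked against
  truth;
* CSS pRF voxel series come from the forward model in :mod:`facegrad.prf`.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axis import AnatomicalAxis, project_to_axis
from .glm import BetaMap, DesignMatrix, HRFParams
from .prf import ApertureStack, CSSParams, css_response

__all__ = [
    "CorticalPatch",
    "GroundTruth",
    "make_patch",
    "make_volume_patch",
    "simulate_betas",
    "simulate_run_betas",
    "simulate_timeseries",
    "simulate_css_voxels",
]

#: intercept (raw signal) level assigned to simulated voxels; with this
#: convention percent signal change equals the beta value numerically.
BASELINE_SIGNAL = 100.0


@dataclass
class CorticalPatch:
    """A grid of vertices with mm coordinates and neighbor adjacency."""

    vertex_ids: np.ndarray
    coords: np.ndarray
    adjacency: dict[int, list[int]]
    grid_shape: tuple[int, ...] = ()
    spacing_mm: float = 1.2

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.vertex_ids.tolist())) != self.vertex_ids.size:
            raise ValueError("vertex_ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for v, nbs in self.adjacency.items():
            for nb in nbs:
                if v not in self.adjacency.get(nb, ()):
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_ids.size)

    def to_frame(self) -> pd.DataFrame:
        cols = {"vertex_id": self.vertex_ids}
        for d, name in zip(range(self.coords.shape[1]), ("x_mm", "y_mm", "z_mm")):
            cols[name] = self.coords[:, d]
        return pd.DataFrame(cols)


def make_patch(n_rows: int, n_cols: int, spacing_mm: float = 1.2) -> CorticalPatch:
    """Regular 2-D grid patch, vertices row-major, 4-neighbor connectivity.

    Vertex (r, c) sits at (c*spacing, r*spacing) mm, so the x axis runs
    along columns.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack([cc.ravel() * spacing_mm, rr.ravel() * spacing_mm])
    ids = np.arange(n_rows * n_cols)
    adj: dict[int, list[int]] = {int(i): [] for i in ids}
    for r in range(n_rows):
        for c in range(n_cols):
            v = r * n_cols + c
            if c + 1 < n_cols:
                adj[v].append(v + 1)
                adj[v + 1].append(v)
            if r + 1 < n_rows:
                adj[v].append(v + n_cols)
                adj[v + n_cols].append(v)
    return CorticalPatch(
        vertex_ids=ids, coords=coords, adjacency=adj,
        grid_shape=(n_rows, n_cols), spacing_mm=spacing_mm,
    )


def make_volume_patch(
    nx: int, ny: int, nz: int, spacing_mm: float = 1.2
) -> CorticalPatch:
    """Regular 3-D voxel grid with 6-neighbor (face) connectivity."""
    if min(nx, ny, nz) < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    coords = np.column_stack(
        [ii.ravel() * spacing_mm, jj.ravel() * spacing_mm, kk.ravel() * spacing_mm]
    )
    ids = np.arange(nx * ny * nz)
    adj: dict[int, list[int]] = {int(i): [] for i in ids}

    def lin(i, j, k):
        return (i * ny + j) * nz + k

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = lin(i, j, k)
                if i + 1 < nx:
                    adj[v].append(lin(i + 1, j, k)); adj[lin(i + 1, j, k)].append(v)
                if j + 1 < ny:
                    adj[v].append(lin(i, j + 1, k)); adj[lin(i, j + 1, k)].append(v)
                if k + 1 < nz:
                    adj[v].append(lin(i, j, k + 1)); adj[lin(i, j, k + 1)].append(v)
    return CorticalPatch(
        vertex_ids=ids, coords=coords, adjacency=adj,
        grid_shape=(nx, ny, nz), spacing_mm=spacing_mm,
    )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic subject's beta patterns.

    ``gradient_slopes`` maps condition name -> slope in response units
    (percent signal change) per mm of axis position.  ``vein_ids`` mark
    voxels whose amplitudes are inflated by ``vein_boost`` so that their
    face-condition PSC exceeds the 4% exclusion threshold by construction.
    """

    baseline_pattern: np.ndarray
    gradient_slopes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    vein_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    vein_boost: float = 6.0
    seed: int = 0
    #: additive condition amplitude, scalar or per-voxel array (e.g. a
    #: face-selective blob that the localizer contrast should recover)
    condition_offsets: dict[str, float | np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline_pattern = np.asarray(self.baseline_pattern, dtype=float)
        self.vein_ids = np.asarray(self.vein_ids, dtype=int)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not all(np.isfinite(list(self.gradient_slopes.values()) or [0.0])):
            raise ValueError("gradient slopes must be finite")
        if self.vein_boost <= 4.0 and self.vein_ids.size:
            raise ValueError("vein_boost must push PSC above the 4% threshold")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "baseline_pattern": self.baseline_pattern.tolist(),
                    "gradient_slopes": self.gradient_slopes,
                    "noise_sd": self.noise_sd,
                    "vein_ids": self.vein_ids.tolist(),
                    "vein_boost": self.vein_boost,
                    "condition_offsets": {
                        k: np.asarray(v).tolist()
                        for k, v in self.condition_offsets.items()
                    },
                    "seed": self.seed,
                },
                fh,
            )


def _check_truth(patch: CorticalPatch, truth: GroundTruth, conditions) -> None:
    if truth.baseline_pattern.shape[0] != patch.n_vertices:
        raise ValueError("baseline_pattern length must match patch size")
    if not set(truth.vein_ids.tolist()) <= set(patch.vertex_ids.tolist()):
        raise ValueError("vein_ids must be patch vertices")
    unknown = set(truth.gradient_slopes) - set(conditions)
    if unknown:
        raise ValueError(f"slope map names unknown conditions: {sorted(unknown)}")
    unknown = set(truth.condition_offsets) - set(conditions)
    if unknown:
        raise ValueError(f"offset map names unknown conditions: {sorted(unknown)}")


def simulate_betas(
    patch: CorticalPatch,
    axis: AnatomicalAxis,
    truth: GroundTruth,
    conditions: list[str],
    rng: np.random.Generator | None = None,
) -> BetaMap:
    """One noisy realization of beta patterns: baseline + gradient + noise.

    beta_c(v) = baseline(v) + slope_c * position(v) + Normal(0, noise_sd²),
    with vein voxels additionally boosted in every condition.  Positions
    are arc-length projections onto the axis.  Betas are on the percent
    signal change scale (intercept fixed at 100).
    """
    if not conditions:
        raise ValueError("conditions must be non-empty")
    _check_truth(patch, truth, conditions)
    lo = patch.coords.min(axis=0) - 1e-9
    hi = patch.coords.max(axis=0) + 1e-9
    if not np.any(np.all((axis.polyline >= lo) & (axis.polyline <= hi), axis=1)):
        raise ValueError("axis does not intersect the patch bounding box")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    pos, _ = project_to_axis(patch.coords, axis)
    beta = np.empty((patch.n_vertices, len(conditions)))
    vein_mask = np.isin(patch.vertex_ids, truth.vein_ids)
    for j, cond in enumerate(conditions):
        slope = truth.gradient_slopes.get(cond, 0.0)
        clean = truth.baseline_pattern + slope * pos \
            + np.asarray(truth.condition_offsets.get(cond, 0.0), dtype=float)
        noise = rng.normal(0.0, truth.noise_sd, size=patch.n_vertices) \
            if truth.noise_sd > 0 else 0.0
        beta[:, j] = clean + noise
        beta[vein_mask, j] += truth.vein_boost
    return BetaMap(
        voxel_ids=patch.vertex_ids.copy(),
        conditions=list(conditions),
        beta=beta,
        baseline=np.full(patch.n_vertices, BASELINE_SIGNAL),
    )


def simulate_run_betas(
    patch: CorticalPatch,
    axis: AnatomicalAxis,
    truth: GroundTruth,
    conditions: list[str],
    n_runs: int = 8,
) -> list[BetaMap]:
    """Independent noisy beta realizations for each run, one shared truth."""
    rng = np.random.default_rng(truth.seed)
    return [
        simulate_betas(patch, axis, truth, conditions, rng=rng)
        for _ in range(n_runs)
    ]


def simulate_timeseries(
    design: DesignMatrix,
    betas: BetaMap,
    noise_sd: float = 0.0,
    seed: int = 0,
    ar_rho: float = 0.0,
) -> np.ndarray:
    """Forward block-design model: y = X beta + noise, shape (n_scans, n_voxels).

    Conditions must match between design and BetaMap.  ``ar_rho`` > 0
    draws AR(1) noise instead of white noise (stationary unit-variance
    innovation scaling), off by default.
    """
    if list(design.conditions) != list(betas.conditions):
        raise ValueError(
            f"condition mismatch: design {design.conditions} vs betas {betas.conditions}"
        )
    if not -1 < ar_rho < 1:
        raise ValueError("ar_rho must lie in (-1, 1)")
    n_vox = betas.voxel_ids.size
    coef = np.zeros((len(design.columns), n_vox))
    coef[: len(design.conditions)] = betas.beta.T
    from .glm import INTERCEPT

    coef[design.columns.index(INTERCEPT)] = betas.baseline
    Y = design.matrix @ coef
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=Y.shape)
        if ar_rho != 0.0:
            out = np.empty_like(eps)
            scale = np.sqrt(1.0 - ar_rho**2)
            out[0] = eps[0]
            for t in range(1, eps.shape[0]):
                out[t] = ar_rho * out[t - 1] + scale * eps[t]
            eps = out
        Y = Y + eps
    return Y


def simulate_css_voxels(
    apertures: ApertureStack,
    params: list[CSSParams],
    noise_sd: float = 0.0,
    seed: int = 0,
    hrf: HRFParams = HRFParams(),
) -> np.ndarray:
    """CSS forward model + Gaussian noise for a set of voxels, (T, n_voxels)."""
    r = apertures.radius_deg
    for p in params:
        if not (abs(p.x) <= r and abs(p.y) <= r):
            raise ValueError(
                f"pRF center ({p.x}, {p.y}) outside the stimulated field"
            )
    series = np.column_stack([css_response(apertures, p, hrf) for p in params])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
    return series
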