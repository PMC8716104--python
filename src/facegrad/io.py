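"""NIfTI and tabular input/output helpers.

Grid patches map one-to-one onto image voxels (row-major), so beta maps
and time series simulated on a patch round-trip through NIfTI volumes
with the patch spacing in the affine.  Tabular formats (TSV) are handled
on the dataclasses themselves (``to_tsv``/``from_tsv``); these helpers
cover the volumetric side.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .glm import BetaMap
from .synthetic import CorticalPatch

__all__ = [
    "patch_affine",
    "write_betamap_nifti",
    "read_betamap_nifti",
    "write_timeseries_nifti",
    "read_timeseries_nifti",
]


def patch_affine(patch: CorticalPatch) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = patch.spacing_mm
    return aff


def _vol_shape(patch: CorticalPatch) -> tuple[int, int, int]:
    shape = tuple(patch.grid_shape)
    if len(shape) == 2:
        shape = shape + (1,)
    if len(shape) != 3:
        raise ValueError("patch has no usable grid shape for volumetric export")
    return shape  # type: ignore[return-value]


def write_betamap_nifti(betas: BetaMap, patch: CorticalPatch, outdir) -> list[Path]:
    """One 3-D volume per condition plus a baseline volume; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shape = _vol_shape(patch)
    aff = patch_affine(patch)
    paths = []
    for cond in betas.conditions + ["baseline"]:
        vals = betas.baseline if cond == "baseline" else betas.get(cond)
        vol = np.asarray(vals, dtype=np.float64).reshape(shape)
        path = outdir / f"beta_{cond}.nii"
        nib.save(nib.Nifti1Image(vol, aff), str(path))
        paths.append(path)
    return paths


def read_betamap_nifti(indir, conditions: list[str]) -> BetaMap:
    indir = Path(indir)
    cols = []
    for cond in conditions:
        img = nib.load(str(indir / f"beta_{cond}.nii"))
        cols.append(np.asarray(img.dataobj, dtype=float).ravel())
    base_path = indir / "beta_baseline.nii"
    if base_path.exists():
        baseline = np.asarray(nib.load(str(base_path)).dataobj, dtype=float).ravel()
    else:
        baseline = np.full(cols[0].size, np.nan)
    beta = np.column_stack(cols)
    return BetaMap(
        voxel_ids=np.arange(beta.shape[0]),
        conditions=list(conditions),
        beta=beta,
        baseline=baseline,
    )


def write_timeseries_nifti(series: np.ndarray, patch: CorticalPatch, path) -> Path:
    """(n_scans, n_voxels) -> 4-D NIfTI with time last."""
    shape = _vol_shape(patch)
    vol = np.moveaxis(
        np.asarray(series, dtype=np.float64), 0, -1
    ).reshape(shape + (series.shape[0],))
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, patch_affine(patch)), str(path))
    return path


def read_timeseries_nifti(path) -> np.ndarray:
    """4-D NIfTI -> (n_scans, n_voxels) array, voxels row-major."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D time-series image")
    return data.reshape(-1, data.shape[-1]).T
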