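"""Pattern normalization, contrasts, and shared-pattern removal.

A condition's multivoxel response pattern mixes the part-specific signal
of interest with a general spatial profile shared by every condition
(vascular density, intrinsic BOLD sensitivity).  Normalization (z-scoring
across voxels) removes overall amplitude differences between conditions;
regressing the whole-face or object pattern out of each part pattern
removes the shared profile, leaving residuals that carry only the
part-specific spatial bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, ZeroVarianceError

__all__ = ["Pattern", "normalize_pattern", "contrast_map", "regress_out"]


@dataclass
class Pattern:
    """Per-voxel response values for one condition."""

    voxel_ids: np.ndarray
    values: np.ndarray
    condition: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_ids.shape[0] != self.values.shape[0]:
            raise ValueError("voxel_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.voxel_ids, "value": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_aligned(a: Pattern, b: Pattern) -> None:
    if len(a) != len(b) or not np.array_equal(a.voxel_ids, b.voxel_ids):
        raise AlignmentError(
            f"patterns {a.condition!r} and {b.condition!r} have different voxel sets"
        )


def normalize_pattern(p: Pattern, method: str = "zscore") -> Pattern:
    """Remove overall amplitude: z-score across voxels (mean 0, SD 1, ddof=1).

    ``method="mean"`` divides by the mean instead; the downstream gradient
    correlation is invariant to this choice because Pearson r is unchanged
    by any sign-preserving affine rescaling of the pattern.
    """
    if len(p) < 3:
        raise ValueError("need at least 3 voxels to normalize a pattern")
    sd = p.values.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(f"pattern {p.condition!r} is constant")
    if method == "zscore":
        vals = (p.values - p.values.mean()) / sd
    elif method == "mean":
        m = p.values.mean()
        if m == 0:
            raise ZeroVarianceError(f"pattern {p.condition!r} has zero mean")
        vals = p.values / m
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(p, values=vals, normalized=True)


def contrast_map(a: Pattern, b: Pattern) -> Pattern:
    """Voxelwise difference a - b of two normalized patterns."""
    if not (a.normalized and b.normalized):
        raise ValueError("contrast_map requires normalized patterns")
    _check_aligned(a, b)
    return Pattern(
        voxel_ids=a.voxel_ids.copy(),
        values=a.values - b.values,
        condition=f"{a.condition}_minus_{b.condition}",
        normalized=False,
    )


def regress_out(part: Pattern, general: Pattern) -> tuple[Pattern, float]:
    """Remove the shared spatial profile from a part pattern by simple OLS.

    Fits part = slope*general + intercept across voxels and returns the
    residual pattern together with R^2 (the fraction of part-pattern
    variance the general pattern explains).  Residuals are exactly
    uncorrelated with the general pattern.
    """
    _check_aligned(part, general)
    g = general.values
    y = part.values
    var_g = g.var(ddof=0)
    if var_g == 0:
        raise ZeroVarianceError(f"general pattern {general.condition!r} is constant")
    slope = np.cov(g, y, ddof=0)[0, 1] / var_g
    intercept = y.mean() - slope * g.mean()
    resid = y - (slope * g + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    residual = Pattern(
        voxel_ids=part.voxel_ids.copy(),
        values=resid,
        condition=f"{part.condition}_residual",
        normalized=False,
    )
    return residual, float(r2)
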