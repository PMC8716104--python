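"""Group-level inference and split-half reliability.

Per-subject gradient correlations are tested against zero with a
one-sample t on the raw r values (two-sided), and the effect size is
Cohen's d = mean(r)/sd(r), the convention under which the headline
pFFA effect is a very large d.  Fisher z-transforming the correlations
first is available as an option; it changes t only slightly for
moderate r and never its sign.

Split-half reliability estimates pattern stability: the per-voxel
condition contrast (e.g. eyes - mouth) is averaged separately over odd
and even runs and the two half-maps are correlated across voxels.  With
signal variance s2 and independent half-noise variance n2 the expected
correlation is the attenuation ratio s2/(s2 + n2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import IncompleteDataError, InsufficientDataError, ZeroVarianceError
from .glm import BetaMap

__all__ = [
    "GradientStats",
    "group_onesample_t",
    "paired_condition_t",
    "split_half_reliability",
    "bonferroni",
]


@dataclass
class GradientStats:
    """Group summary of per-subject gradient correlations."""

    per_subject_r: np.ndarray
    t: float
    df: int
    p: float
    cohens_d: float

    def summary(self) -> str:
        return (
            f"mean r = {self.per_subject_r.mean():+.3f}, "
            f"t({self.df}) = {self.t:.2f}, p = {self.p:.4g}, "
            f"Cohen's d = {self.cohens_d:.2f}"
        )


def group_onesample_t(
    rs: Sequence[float], fisher_z: bool = False
) -> GradientStats:
    """One-sample t of per-subject correlations against zero (two-sided).

    Cohen's d = mean/sd of the tested values.  With ``fisher_z`` the t is
    computed on arctanh(r); the reported per_subject_r stay on the r scale.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size < 2:
        raise InsufficientDataError("group test needs at least 2 subjects")
    x = np.arctanh(rs) if fisher_z else rs
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("per-subject values are identical")
    n = x.size
    t = x.mean() / (sd / np.sqrt(n))
    p = 2.0 * sp_stats.t.sf(abs(t), df=n - 1)
    return GradientStats(
        per_subject_r=rs,
        t=float(t),
        df=n - 1,
        p=float(p),
        cohens_d=float(x.mean() / sd),
    )


def paired_condition_t(
    amplitudes: pd.DataFrame, a: str, b: str
) -> tuple[float, int, float]:
    """Paired t across subjects between two condition columns: (t, df, p two-sided)."""
    for c in (a, b):
        if c not in amplitudes.columns:
            raise IncompleteDataError(f"condition {c!r} missing from table")
    sub = amplitudes[[a, b]]
    if sub.isna().any().any():
        raise IncompleteDataError("amplitude table has missing cells")
    d = (sub[a] - sub[b]).to_numpy(dtype=float)
    if d.size < 2:
        raise InsufficientDataError("paired t needs at least 2 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, d.size - 1, 1.0
        raise ZeroVarianceError("constant nonzero difference between conditions")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * sp_stats.t.sf(abs(t), df=d.size - 1)
    return float(t), d.size - 1, float(p)


def split_half_reliability(
    betas_by_run: Sequence[BetaMap], cond_a: str, cond_b: str
) -> float:
    """Odd/even split-half correlation of the per-voxel (a - b) contrast.

    Runs are 1-based: runs 1,3,5,... form the odd half.  The contrast is
    averaged within each half and the two half-maps are Pearson-correlated
    across voxels.
    """
    if len(betas_by_run) < 2:
        raise InsufficientDataError("split-half needs at least 2 runs")
    vox = betas_by_run[0].voxel_ids
    if vox.size < 3:
        raise InsufficientDataError("split-half needs at least 3 voxels")
    for bm in betas_by_run[1:]:
        if not np.array_equal(bm.voxel_ids, vox):
            raise ValueError("all runs must share the same voxel set")
    biases = np.stack([bm.get(cond_a) - bm.get(cond_b) for bm in betas_by_run])
    odd = biases[0::2].mean(axis=0)
    even = biases[1::2].mean(axis=0)
    if np.ptp(odd) == 0 or np.ptp(even) == 0:
        raise ZeroVarianceError("constant contrast in one half")
    r, _ = sp_stats.pearsonr(odd, even)
    return float(r)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values (clipped at 1); off by default in the pipeline."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)
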