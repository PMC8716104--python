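"""Block-design GLM estimation with a two-parameter gamma HRF.

The hemodynamic response is modelled by the Boynton-style gamma

    h(t) = ((t - delta) / tau)^2 * exp(-(t - delta) / tau)   for t >= delta

(zero before the onset delay ``delta``), rescaled to unit peak.  The peak
of x^2 e^{-x} sits at x = 2, so the response peaks at ``delta + 2*tau``
seconds — 4.75 s for the default (delta=2.25 s, tau=1.25 s).

Each stimulus condition contributes a boxcar regressor matched to the
block duration, sampled on the TR grid and convolved with the HRF; the
design always carries an explicit intercept that estimates the baseline
signal, from which percent signal change is derived as 100*beta/baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RankDeficientError

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "BetaMap",
    "gamma_hrf",
    "build_design",
    "fit_glm",
]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class HRFParams:
    """Gamma HRF parameters: onset delay ``delta`` (s) and time constant ``tau`` (s)."""

    delta: float = 2.25
    tau: float = 1.25
    #: "peak" scales h to max 1; "area" scales to unit sum on the sampling grid.
    normalize: str = "peak"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if self.normalize not in ("peak", "area"):
            raise ValueError(f"normalize must be 'peak' or 'area', got {self.normalize!r}")


def gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the gamma HRF on a time grid (seconds).

    Returns the unit-peak response h(t) = x^2 e^{-x} with
    x = (t - delta)/tau for t >= delta and 0 before onset.  With
    ``normalize="area"`` the samples are instead scaled to sum to 1, which
    rescales all betas by a common factor and leaves contrasts and
    correlations unchanged.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("t must be a 1-D grid of times")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    x = (t - params.delta) / params.tau
    h = np.where(x >= 0, x**2 * np.exp(-np.clip(x, 0, None)), 0.0)
    if params.normalize == "peak":
        # analytic peak of x^2 e^-x at x=2 -> value 4 e^-2
        h = h / (4.0 * np.exp(-2.0))
    else:
        s = h.sum()
        if s > 0:
            h = h / s
    return h


@dataclass
class DesignMatrix:
    """A sampled block design: one convolved column per condition plus nuisance.

    ``matrix`` has shape (n_scans, n_columns) and ``columns`` names every
    column; condition columns come first, the intercept and any polynomial
    drift columns last.
    """

    conditions: list[str]
    columns: list[str]
    matrix: np.ndarray
    tr: float
    n_scans: int
    blocks: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n_scans, len(self.columns)):
            raise ValueError("matrix shape does not match n_scans x columns")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def boxcar(
    blocks: list[tuple[str, float, float]],
    condition: str,
    tr: float,
    n_scans: int,
) -> np.ndarray:
    """Unconvolved boxcar for one condition sampled at scan acquisition times.

    A scan at time i*TR is inside a block when onset <= i*TR < onset+duration,
    so a 16 s block sampled at TR = 2 s covers exactly 8 scans.  Overlapping
    blocks of the same condition sum.
    """
    t = np.arange(n_scans) * tr
    box = np.zeros(n_scans)
    for cond, onset, duration in blocks:
        if cond != condition:
            continue
        box += ((t >= onset) & (t < onset + duration)).astype(float)
    return box


def build_design(
    blocks: list[tuple[str, float, float]],
    tr: float,
    n_scans: int,
    hrf: HRFParams = HRFParams(),
    drift_order: int | None = None,
    conditions: list[str] | None = None,
) -> DesignMatrix:
    """Build the design matrix for a list of (condition, onset s, duration s) blocks.

    Condition order follows first appearance unless ``conditions`` is given.
    Convolution is discrete on the TR grid and truncated to the run length.
    ``drift_order`` adds Legendre-style polynomial drift columns (the default
    of None matches data whose slow drifts were removed upstream).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    run_len = n_scans * tr
    for cond, onset, duration in blocks:
        if onset < 0:
            raise ValueError(f"negative onset {onset} for condition {cond!r}")
        if duration <= 0:
            raise ValueError(f"non-positive duration {duration} for condition {cond!r}")
        if onset + duration > run_len + 1e-9:
            raise ValueError(
                f"block ({cond!r}, {onset}, {duration}) extends past run end {run_len}"
            )
    if conditions is None:
        conditions = list(dict.fromkeys(cond for cond, _, _ in blocks))
    else:
        unknown = {c for c, _, _ in blocks} - set(conditions)
        if unknown:
            raise ValueError(f"blocks contain conditions not listed: {sorted(unknown)}")

    h = gamma_hrf(np.arange(n_scans) * tr, hrf)
    cols = []
    for cond in conditions:
        box = boxcar(blocks, cond, tr, n_scans)
        cols.append(np.convolve(box, h)[:n_scans])
    cols.append(np.ones(n_scans))
    names = list(conditions) + [INTERCEPT]
    if drift_order is not None:
        # orthogonal polynomials in scan index, degree 1..drift_order
        x = np.linspace(-1, 1, n_scans)
        for k in range(1, drift_order + 1):
            p = np.polynomial.legendre.Legendre.basis(k)(x)
            cols.append(p)
            names.append(f"drift{k}")
    return DesignMatrix(
        conditions=list(conditions),
        columns=names,
        matrix=np.column_stack(cols),
        tr=tr,
        n_scans=n_scans,
        blocks=list(blocks),
    )


@dataclass
class BetaMap:
    """Per-voxel GLM amplitude estimates for a set of conditions.

    ``beta`` has shape (n_voxels, n_conditions); ``baseline`` is the
    intercept estimate per voxel.  Percent signal change is
    100*beta/baseline and is NaN where the baseline is not positive.
    """

    voxel_ids: np.ndarray
    conditions: list[str]
    beta: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        n_vox = self.voxel_ids.shape[0]
        if self.beta.shape != (n_vox, len(self.conditions)):
            raise ValueError("beta shape must be (n_voxels, n_conditions)")
        if self.baseline.shape != (n_vox,):
            raise ValueError("baseline must be one value per voxel")

    def get(self, condition: str) -> np.ndarray:
        """Beta values for one condition across voxels."""
        return self.beta[:, self.conditions.index(condition)]

    @property
    def psc(self) -> np.ndarray:
        """Percent signal change, (n_voxels, n_conditions); NaN where baseline <= 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * self.beta / self.baseline[:, None]
        out[self.baseline <= 0] = np.nan
        return out

    def psc_for(self, condition: str) -> np.ndarray:
        return self.psc[:, self.conditions.index(condition)]

    def subset(self, voxel_ids) -> "BetaMap":
        """Restrict to the given voxel ids, preserving their order here."""
        idx = {int(v): i for i, v in enumerate(self.voxel_ids)}
        rows = np.array([idx[int(v)] for v in voxel_ids], dtype=int)
        return BetaMap(
            voxel_ids=np.asarray(voxel_ids),
            conditions=list(self.conditions),
            beta=self.beta[rows],
            baseline=self.baseline[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"voxel_id": self.voxel_ids})
        for j, cond in enumerate(self.conditions):
            df[cond] = self.beta[:, j]
        df["baseline"] = self.baseline
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMap":
        conds = [c for c in df.columns if c not in ("voxel_id", "baseline")]
        return cls(
            voxel_ids=df["voxel_id"].to_numpy(),
            conditions=conds,
            beta=df[conds].to_numpy(dtype=float),
            baseline=df["baseline"].to_numpy(dtype=float),
        )

    @classmethod
    def from_tsv(cls, path) -> "BetaMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    voxel_ids: np.ndarray | None = None,
) -> BetaMap:
    """Ordinary least squares fit of every voxel time course.

    ``series`` has shape (n_scans, n_voxels).  A rank-deficient design
    raises :class:`RankDeficientError` rather than silently falling back
    to a pseudo-inverse, because collinear condition regressors make the
    condition amplitudes meaningless.
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n_scans:
        raise ValueError(
            f"series has {Y.shape[0]} scans but design expects {design.n_scans}"
        )
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} columns"
        )
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    n_cond = len(design.conditions)
    beta = coef[:n_cond].T
    baseline = coef[design.columns.index(INTERCEPT)]
    if voxel_ids is None:
        voxel_ids = np.arange(Y.shape[1])
    return BetaMap(
        voxel_ids=np.asarray(voxel_ids),
        conditions=list(design.conditions),
        beta=beta,
        baseline=baseline,
    )
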