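"""Compressive spatial summation (CSS) pRF model with wedge/ring apertures.

The CSS model predicts a voxel's response to a binary stimulus aperture
as the overlap between the aperture and an isotropic 2-D Gaussian
receptive field, passed through a static power-law nonlinearity:

    r(t) = gain * ( sum_pixels  A_t(px) * G_{x,y,sigma}(px) )^n

with G normalized to unit sum over the pixel grid (so a full-field
stimulus with n = 1 yields exactly ``gain``), then convolved with the
gamma HRF.  Exponents n < 1 compress responses to partial-field stimuli,
the signature of spatial summation in higher visual areas.

Stimuli follow the classic travelling-aperture retinotopy protocol:
a 45-degree wedge revolving once per 32 s (clockwise or counterclockwise)
and an expanding or contracting ring sweeping for 28 s followed by 4 s of
rest, all inside a 10-degree-radius field.

Fitting is a dense grid search over (x, y, sigma, n) with the gain and an
additive offset solved by least squares, optionally followed by
Nelder-Mead refinement of the continuous parameters.  Model fitness is
the coefficient of determination against the mean-only model, reported
in percent; voxels are kept only when R^2 exceeds 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .glm import HRFParams, gamma_hrf

__all__ = [
    "ApertureStack",
    "CSSParams",
    "make_wedge_apertures",
    "make_ring_apertures",
    "css_response",
    "CSSPredictorBank",
    "build_predictor_bank",
    "fit_css",
    "filter_by_r2",
]

DEFAULT_RADIUS_DEG = 10.0
DEFAULT_GRID_PIXELS = 64


@dataclass
class ApertureStack:
    """Binary stimulus masks over time on a square pixel grid.

    ``frames`` is (n_frames, n_pixels) with values in {0,1}; ``x``/``y``
    give each pixel's center in degrees of visual angle.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tr: float
    radius_deg: float = DEFAULT_RADIUS_DEG

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 2:
            raise ValueError("frames must be (n_frames, n_pixels)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("aperture frames must be binary")
        if self.frames.shape[1] != self.x.size or self.x.size != self.y.size:
            raise ValueError("pixel grid size mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def concat(self, other: "ApertureStack") -> "ApertureStack":
        """Stack two runs in time (grids must match)."""
        if self.tr != other.tr or self.x.size != other.x.size:
            raise ValueError("cannot concatenate stacks with different grids/TR")
        return replace(self, frames=np.vstack([self.frames, other.frames]))


def _pixel_grid(n_pix: int, radius_deg: float) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(n_pix) + 0.5) / n_pix * 2 * radius_deg - radius_deg
    X, Y = np.meshgrid(c, c)
    return X.ravel(), Y.ravel()


def _check_multiple(value: float, tr: float, what: str) -> int:
    k = value / tr
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"{what} ({value} s) must be a multiple of TR ({tr} s)")
    return int(round(k))


def make_wedge_apertures(
    span_deg: float = 45.0,
    period_s: float = 32.0,
    direction: str = "ccw",
    radius_deg: float = DEFAULT_RADIUS_DEG,
    tr: float = 2.0,
    n_cycles: int = 1,
    n_pix: int = DEFAULT_GRID_PIXELS,
    blank_s: float = 0.0,
) -> ApertureStack:
    """Rotating wedge apertures sampled once per TR.

    The wedge center starts on the positive x-axis and advances
    span-uniformly through ``period_s`` per revolution; ``direction``
    sets the rotation sign ("ccw" or "cw").  ``blank_s`` prepends and
    appends all-zero fixation frames.
    """
    if not 0 < span_deg < 360:
        raise ValueError("wedge span must be in (0, 360) degrees")
    if direction not in ("cw", "ccw"):
        raise ValueError("direction must be 'cw' or 'ccw'")
    frames_per_cycle = _check_multiple(period_s, tr, "wedge period")
    n_blank = _check_multiple(blank_s, tr, "blank duration") if blank_s else 0
    x, y = _pixel_grid(n_pix, radius_deg)
    rad = np.hypot(x, y)
    ang = np.arctan2(y, x)
    in_disk = rad <= radius_deg
    sign = 1 if direction == "ccw" else -1
    half = np.deg2rad(span_deg) / 2.0
    frames = []
    for i in range(frames_per_cycle * n_cycles):
        # reduce the index first so cw frame i and ccw frame N-i share the
        # exact same float angle (bitwise-equal masks under time reversal)
        theta = 2 * np.pi * ((sign * i) % frames_per_cycle) / frames_per_cycle
        delta = np.angle(np.exp(1j * (ang - theta)))
        frames.append((in_disk & (np.abs(delta) <= half)).astype(np.uint8))
    stack = np.asarray(frames)
    if n_blank:
        z = np.zeros((n_blank, stack.shape[1]), dtype=np.uint8)
        stack = np.vstack([z, stack, z])
    return ApertureStack(frames=stack, x=x, y=y, tr=tr, radius_deg=radius_deg)


def make_ring_apertures(
    sweep_s: float = 28.0,
    rest_s: float = 4.0,
    radius_deg: float = DEFAULT_RADIUS_DEG,
    tr: float = 2.0,
    n_cycles: int = 1,
    direction: str = "expand",
    n_pix: int = DEFAULT_GRID_PIXELS,
    blank_s: float = 0.0,
) -> ApertureStack:
    """Expanding/contracting ring apertures: sweep then rest, per cycle.

    During the sweep an annulus of constant thickness radius/n_sweep moves
    from fovea to periphery (or the reverse); the rest frames are blank.
    """
    if direction not in ("expand", "contract"):
        raise ValueError("direction must be 'expand' or 'contract'")
    n_sweep = _check_multiple(sweep_s, tr, "ring sweep")
    n_rest = _check_multiple(rest_s, tr, "ring rest")
    n_blank = _check_multiple(blank_s, tr, "blank duration") if blank_s else 0
    x, y = _pixel_grid(n_pix, radius_deg)
    rad = np.hypot(x, y)
    edges = np.linspace(0, radius_deg, n_sweep + 1)
    sweep = [
        ((rad >= edges[k]) & (rad < edges[k + 1])).astype(np.uint8)
        for k in range(n_sweep)
    ]
    if direction == "contract":
        sweep = sweep[::-1]
    cycle = np.vstack([sweep, np.zeros((n_rest, x.size), dtype=np.uint8)])
    stack = np.vstack([cycle] * n_cycles)
    if n_blank:
        z = np.zeros((n_blank, stack.shape[1]), dtype=np.uint8)
        stack = np.vstack([z, stack, z])
    return ApertureStack(frames=stack, x=x, y=y, tr=tr, radius_deg=radius_deg)


@dataclass
class CSSParams:
    """CSS pRF parameters: center (x, y) deg, size sigma deg, exponent n, gain, R² %."""

    x: float
    y: float
    sigma: float
    n: float
    gain: float = 1.0
    r2: float = np.nan

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("pRF size sigma must be positive")
        if self.n <= 0:
            raise ValueError("CSS exponent n must be positive")


def _gaussian_field(x: np.ndarray, y: np.ndarray, cx: float, cy: float,
                    sigma: float) -> np.ndarray:
    g = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def css_drive(apertures: ApertureStack, p: CSSParams) -> np.ndarray:
    """Aperture-Gaussian overlap per frame raised to the exponent, times gain."""
    if apertures.n_frames == 0:
        raise ValueError("empty aperture stack")
    g = _gaussian_field(apertures.x, apertures.y, p.x, p.y, p.sigma)
    overlap = apertures.frames @ g
    return p.gain * overlap**p.n


def css_response(
    apertures: ApertureStack,
    p: CSSParams,
    hrf: HRFParams | None = HRFParams(),
) -> np.ndarray:
    """Predicted BOLD time series of a CSS voxel; ``hrf=None`` skips convolution."""
    drive = css_drive(apertures, p)
    if hrf is None:
        return drive
    h = gamma_hrf(np.arange(apertures.n_frames) * apertures.tr, hrf)
    return signal.fftconvolve(drive, h)[: apertures.n_frames]


# -- fitting -----------------------------------------------------------------

DEFAULT_XS = np.linspace(-9.0, 9.0, 13)
DEFAULT_YS = np.linspace(-9.0, 9.0, 13)
DEFAULT_SIGMAS = np.array([0.5, 1.0, 1.5, 2.5, 4.0, 6.0, 8.0])
DEFAULT_EXPONENTS = np.array([0.25, 0.5, 0.75, 1.0])


@dataclass
class CSSPredictorBank:
    """Precomputed HRF-convolved CSS predictions on a parameter grid.

    ``params`` is (K, 4) columns (x, y, sigma, n); ``pred`` is (T, K);
    ``unit`` is the column-centered unit-norm version used for the
    correlation screen.
    """

    params: np.ndarray
    pred: np.ndarray
    unit: np.ndarray
    apertures: ApertureStack
    hrf: HRFParams


def build_predictor_bank(
    apertures: ApertureStack,
    hrf: HRFParams = HRFParams(),
    xs: np.ndarray = DEFAULT_XS,
    ys: np.ndarray = DEFAULT_YS,
    sigmas: np.ndarray = DEFAULT_SIGMAS,
    exponents: np.ndarray = DEFAULT_EXPONENTS,
) -> CSSPredictorBank:
    """Vectorized construction of the grid-search predictor bank."""
    px, py = apertures.x, apertures.y
    centers = [(cx, cy, s) for cx in xs for cy in ys for s in sigmas]
    G = np.empty((px.size, len(centers)))
    for j, (cx, cy, s) in enumerate(centers):
        G[:, j] = _gaussian_field(px, py, cx, cy, s)
    overlap = apertures.frames.astype(float) @ G  # (T, n_centers)
    h = gamma_hrf(np.arange(apertures.n_frames) * apertures.tr, hrf)
    preds, params = [], []
    for n in exponents:
        resp = overlap**n
        conv = signal.fftconvolve(resp, h[:, None], axes=0)[: apertures.n_frames]
        preds.append(conv)
        params.extend([(cx, cy, s, n) for (cx, cy, s) in centers])
    pred = np.hstack(preds)
    centered = pred - pred.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    norms[norms == 0] = 1.0
    return CSSPredictorBank(
        params=np.asarray(params),
        pred=pred,
        unit=centered / norms,
        apertures=apertures,
        hrf=hrf,
    )


def _gain_offset_r2(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([pred, np.ones_like(pred)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 100.0 * (1.0 - resid @ resid / ss_tot) if ss_tot > 0 else 0.0
    return float(coef[0]), float(coef[1]), float(r2)


def _refine(
    y: np.ndarray,
    start: np.ndarray,
    apertures: ApertureStack,
    hrf: HRFParams,
) -> np.ndarray:
    """Nelder-Mead on (x, y, log sigma, log n), maximizing correlation."""
    frames = apertures.frames.astype(float)
    h = gamma_hrf(np.arange(apertures.n_frames) * apertures.tr, hrf)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)

    def neg_corr(theta: np.ndarray) -> float:
        cx, cy, ls, ln = theta
        sigma, n = np.exp(ls), np.exp(ln)
        if sigma > 20 or sigma < 1e-3 or n > 4 or n < 0.05:
            return 1.0
        g = _gaussian_field(apertures.x, apertures.y, cx, cy, sigma)
        resp = (frames @ g) ** n
        pred = signal.fftconvolve(resp, h)[: apertures.n_frames]
        pc = pred - pred.mean()
        denom = np.linalg.norm(pc) * ynorm
        if denom == 0:
            return 1.0
        return 1.0 - float(pc @ yc) / denom

    x0 = np.array([start[0], start[1], np.log(start[2]), np.log(start[3])])
    res = optimize.minimize(
        neg_corr, x0, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400},
    )
    cx, cy, ls, ln = res.x
    return np.array([cx, cy, np.exp(ls), np.exp(ln)])


def fit_css(
    series: np.ndarray,
    apertures: ApertureStack | None = None,
    hrf: HRFParams = HRFParams(),
    bank: CSSPredictorBank | None = None,
    refine: bool = True,
) -> CSSParams | list[CSSParams]:
    """Fit the CSS model per voxel: grid screen + optional local refinement.

    ``series`` is (T,) for one voxel or (T, V).  Passing a prebuilt
    ``bank`` amortizes the grid predictions across voxels.  A flat series
    returns gain 0, R² 0 rather than an error.  Returns a single
    :class:`CSSParams` for 1-D input, else one per voxel.
    """
    if bank is None:
        if apertures is None:
            raise ValueError("provide either apertures or a predictor bank")
        bank = build_predictor_bank(apertures, hrf)
    apertures = bank.apertures
    hrf = bank.hrf
    Y = np.asarray(series, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    if Y.shape[0] != apertures.n_frames:
        raise ValueError("series length must equal the number of aperture frames")
    out: list[CSSParams] = []
    Yc = Y - Y.mean(axis=0)
    norms = np.linalg.norm(Yc, axis=0)
    corr = bank.unit.T @ (Yc / np.where(norms == 0, 1.0, norms))  # (K, V)
    for v in range(Y.shape[1]):
        y = Y[:, v]
        if norms[v] == 0:
            out.append(CSSParams(x=0.0, y=0.0, sigma=1.0, n=1.0, gain=0.0, r2=0.0))
            continue
        if refine:
            # refine from the few best grid cells with distinct centers;
            # Nelder-Mead can stall in a local basin from a single start
            order = np.argsort(corr[:, v])[::-1]
            starts, seen = [], set()
            for k in order:
                key = tuple(bank.params[k][:2])
                if key not in seen:
                    seen.add(key)
                    starts.append(bank.params[k].copy())
                if len(starts) == 3:
                    break
            best_p, best_r2, best_gain = None, -np.inf, 0.0
            for start in starts:
                theta = _refine(y, start, apertures, hrf)
                p = CSSParams(x=theta[0], y=theta[1], sigma=theta[2],
                              n=theta[3])
                pred = css_response(apertures, p, hrf)
                gain, _, r2 = _gain_offset_r2(pred, y)
                if r2 > best_r2:
                    best_p, best_r2, best_gain = p, r2, gain
            out.append(replace(best_p, gain=best_gain, r2=best_r2))
        else:
            theta = bank.params[int(np.argmax(corr[:, v]))]
            p = CSSParams(x=theta[0], y=theta[1], sigma=theta[2], n=theta[3])
            pred = css_response(apertures, p, hrf)
            gain, _, r2 = _gain_offset_r2(pred, y)
            out.append(replace(p, gain=gain, r2=r2))
    return out[0] if single else out


def filter_by_r2(
    fits: Sequence[CSSParams], threshold_pct: float = 2.0
) -> list[CSSParams]:
    """Keep fits with R² strictly above the threshold (in percent)."""
    return [f for f in fits if f.r2 > threshold_pct]
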