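"""Spot detection and 2D Gaussian fitting of frame stacks into orte matrices.

Candidates are local maxima exceeding a robust background threshold
(median + threshold_factor * 1.4826*MAD), then refined by least-squares
fitting of an isotropic 2D Gaussian plus constant offset on a small window.
The per-event localization error is a Thompson-style estimate
sigma / sqrt(N_photons).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .io_masks import OrteMatrix

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Detection/fitting settings; ``threshold_factor`` defaults to 3."""

    threshold_factor: float = 3.0
    fit_window: int = 7
    max_iterations: int = 200
    convergence_tol: float = 0.01  # nm

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.fit_window < 5 or self.fit_window % 2 == 0:
            raise ValueError("fit_window must be odd and >= 5")


@dataclass
class FrameStack:
    """3D stack (frame, row, col) of non-negative photon counts."""

    frames: np.ndarray
    pixel_size_nm: float
    ground_truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, row, col) array")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frame values must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Localization:
    amplitude: float
    x_nm: float
    y_nm: float
    loc_error_nm: float


class FitRejected(Exception):
    """A candidate could not be fitted; ``reason`` goes to the rejection log."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def detect_spots(frame: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Candidate spot pixels of a single frame as an (n, 2) (row, col) array.

    A candidate is an 8-neighborhood local maximum whose value exceeds
    ``median + threshold_factor * 1.4826 * MAD``.  Candidates closer than
    ``fit_window`` pixels (Euclidean) are merged to the brighter one.
    A constant frame yields no candidates.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    threshold = med + params.threshold_factor * 1.4826 * mad

    is_max = frame == ndimage.maximum_filter(frame, size=3, mode="nearest")
    cand = np.argwhere(is_max & (frame > threshold))
    if len(cand) == 0:
        return cand.reshape(0, 2)

    # brighter-first greedy merge of nearby candidates
    order = np.argsort(-frame[cand[:, 0], cand[:, 1]], kind="stable")
    cand = cand[order]
    kept: list[np.ndarray] = []
    for c in cand:
        if all(np.hypot(*(c - k)) >= params.fit_window for k in kept):
            kept.append(c)
    return np.array(kept, dtype=int)


def _gauss_model(p, yy, xx):
    amp, x0, y0, sigma, offset = p
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)) + offset


def _gauss_jac(p, yy, xx):
    amp, x0, y0, sigma, _ = p
    r2 = (xx - x0) ** 2 + (yy - y0) ** 2
    e = np.exp(-r2 / (2.0 * sigma**2))
    cols = [
        e.ravel(),
        (amp * e * (xx - x0) / sigma**2).ravel(),
        (amp * e * (yy - y0) / sigma**2).ravel(),
        (amp * e * r2 / sigma**3).ravel(),
        np.ones(e.size),
    ]
    return np.column_stack(cols)


def fit_gaussian2d(
    frame: np.ndarray,
    candidate,
    params: DetectionParams | None = None,
    pixel_size_nm: float = 100.0,
) -> Localization:
    """Fit an isotropic 2D Gaussian + offset around one candidate pixel.

    Returns the sub-pixel center in nm (pixel i spans [i*p, (i+1)*p)) and a
    Thompson-style localization-error estimate sigma/sqrt(N_photons).
    Raises :class:`FitRejected` for edge candidates, non-convergence, or a
    fitted center that leaves the window.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    half = params.fit_window // 2
    r, c = int(candidate[0]), int(candidate[1])
    if r - half < 0 or c - half < 0 or r + half >= frame.shape[0] or c + half >= frame.shape[1]:
        raise FitRejected("edge")
    win = frame[r - half : r + half + 1, c - half : c + half + 1]
    yy, xx = np.mgrid[r - half : r + half + 1, c - half : c + half + 1]
    yy = yy + 0.5  # pixel centers in continuous pixel coordinates
    xx = xx + 0.5

    offset0 = float(np.median(win))
    amp0 = max(float(win[half, half] - offset0), 1e-3)
    p0 = [amp0, c + 0.5, r + 0.5, 1.3, offset0]
    try:
        res = optimize.least_squares(
            lambda p: (_gauss_model(p, yy, xx) - win).ravel(),
            p0,
            jac=lambda p: _gauss_jac(p, yy, xx),
            method="lm",
            max_nfev=params.max_iterations,
            xtol=max(params.convergence_tol / pixel_size_nm, 1e-12),
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise FitRejected(f"fit-error:{exc.__class__.__name__}") from exc
    if not res.success:
        raise FitRejected("no-convergence")
    amp, x0, y0, sigma, offset = res.x
    sigma = abs(float(sigma))
    if not (c - half <= x0 <= c + half + 1 and r - half <= y0 <= r + half + 1):
        raise FitRejected("center-outside-window")
    if amp <= 0 or not 0.2 <= sigma <= params.fit_window:
        raise FitRejected("degenerate-shape")
    n_photons = max(float((win - offset).sum()), 1.0)
    # Thompson-style precision: pixelation and background terms included
    sigma_a2 = (sigma * pixel_size_nm) ** 2 + pixel_size_nm**2 / 12.0
    bg_var = max(float(offset), 0.0)  # Poisson background: variance = mean
    var_loc = (16.0 / 9.0) * sigma_a2 / n_photons + (
        8.0 * np.pi * sigma_a2**2 * bg_var / (pixel_size_nm**2 * n_photons**2)
    )
    return Localization(
        amplitude=max(float(amp), 1e-12),
        x_nm=float(x0 * pixel_size_nm),
        y_nm=float(y0 * pixel_size_nm),
        loc_error_nm=float(np.sqrt(var_loc)),
    )


def localize_stack(
    stack: FrameStack, params: DetectionParams | None = None, channel: str = ""
) -> OrteMatrix:
    """Detect and fit all frames of a stack; returns the orte matrix.

    Deterministic for fixed input.  Rejection counts are logged per reason.
    """
    params = params or DetectionParams()
    rows = []
    rejections: Counter[str] = Counter()
    for f_idx in range(stack.n_frames):
        frame = stack.frames[f_idx]
        for cand in detect_spots(frame, params):
            try:
                loc = fit_gaussian2d(frame, cand, params, stack.pixel_size_nm)
            except FitRejected as rej:
                rejections[rej.reason] += 1
                continue
            rows.append((loc.amplitude, loc.x_nm, loc.y_nm, loc.loc_error_nm, f_idx))
    if rejections:
        logger.info("localize_stack rejections: %s", dict(rejections))
    data = pd.DataFrame(rows, columns=["amplitude", "x_nm", "y_nm", "loc_error_nm", "frame"])
    return OrteMatrix(data, channel=channel, source="localize_stack")
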