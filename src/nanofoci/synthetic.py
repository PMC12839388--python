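"""Ground-truth two-channel nuclear scenes for end-to-end testing.

The generator produces a disc-shaped nucleus (default area ~30 µm²) with
one or two Gaussian damage foci, clustered two-channel event positions
with a configurable co-localization fraction, uniform background events,
and per-channel Gaussian localization error (defaults 17 nm / 15 nm).
It is a Thomas-process-style stand-in for the raw measurement data, so
every downstream stage can be validated against known structure.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_masks import BinaryMask, OrteMatrix, mask_area
from .localization import FrameStack

logger = logging.getLogger(__name__)

# Disc of radius 3090 nm has area 29.998 µm², matching the typical nucleus.
DEFAULT_NUCLEUS_RADIUS_NM = 3090.0


class PlacementError(RuntimeError):
    """Raised when foci cannot be placed at the required separation."""


@dataclass
class SceneParams:
    """Parameters of a synthetic two-channel nucleus scene.

    Foci events are isotropic Gaussians around the focus centers; a
    ``coloc_fraction`` subset of channel-2 focus events is anchored to a
    channel-1 event position plus a small Gaussian displacement.
    """

    nucleus_radius_nm: float = DEFAULT_NUCLEUS_RADIUS_NM
    n_foci: int = 2
    focus_sigma_nm: float = 50.0
    focus_sigma_ch2_nm: float | None = None  # defaults to focus_sigma_nm
    # macro-focus mask radius; 535 nm puts the default two-focus mask at
    # ~6% of the ~30 um^2 nucleus (macro-foci are much wider than the
    # nanocluster sigma)
    foci_mask_radius_nm: float = 535.0
    events_per_focus_ch1: int = 300
    events_per_focus_ch2: int = 300
    background_density_ch1: float = 50.0  # events per µm²
    background_density_ch2: float = 50.0
    coloc_fraction: float = 0.3
    coloc_displacement_sigma_nm: float = 10.0
    loc_error_ch1_nm: float = 17.0
    loc_error_ch2_nm: float = 15.0
    mask_pixel_nm: float = 20.0
    seed: int = 0

    @property
    def sigma_ch2_nm(self) -> float:
        return self.focus_sigma_ch2_nm if self.focus_sigma_ch2_nm is not None else self.focus_sigma_nm

    def validate(self) -> None:
        if self.nucleus_radius_nm <= 0 or self.focus_sigma_nm <= 0:
            raise ValueError("lengths must be > 0")
        if self.focus_sigma_ch2_nm is not None and self.focus_sigma_ch2_nm <= 0:
            raise ValueError("lengths must be > 0")
        if self.foci_mask_radius_nm <= 0:
            raise ValueError("lengths must be > 0")
        if self.coloc_displacement_sigma_nm < 0 or self.mask_pixel_nm <= 0:
            raise ValueError("lengths must be > 0")
        if min(self.loc_error_ch1_nm, self.loc_error_ch2_nm) < 0:
            raise ValueError("localization errors must be >= 0")
        if self.n_foci < 0 or self.events_per_focus_ch1 < 0 or self.events_per_focus_ch2 < 0:
            raise ValueError("counts must be >= 0")
        if min(self.background_density_ch1, self.background_density_ch2) < 0:
            raise ValueError("background densities must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")


@dataclass
class GroundTruthScene:
    """A realized scene: true emitter positions, labels and the two masks.

    Labels are the focus index for focus events and -1 for background.
    ``anchored_ch2`` flags channel-2 events placed next to a channel-1
    event (the generated co-localization subset); ``anchor_index_ch2``
    holds the row of that channel-1 event (-1 otherwise).
    """

    params: SceneParams
    center_nm: tuple[float, float]
    focus_centers: np.ndarray  # (k, 2) nm
    positions_ch1: np.ndarray  # (n1, 2) nm
    labels_ch1: np.ndarray
    positions_ch2: np.ndarray
    labels_ch2: np.ndarray
    anchored_ch2: np.ndarray
    anchor_index_ch2: np.ndarray
    nucleus_mask: BinaryMask
    foci_mask: BinaryMask

    def positions(self, channel: int) -> np.ndarray:
        if channel == 1:
            return self.positions_ch1
        if channel == 2:
            return self.positions_ch2
        raise ValueError("channel must be 1 or 2")

    def labels(self, channel: int) -> np.ndarray:
        return self.labels_ch1 if channel == 1 else self.labels_ch2


def _build_masks(params: SceneParams, center, focus_centers):
    p = params.mask_pixel_nm
    extent = 2.0 * (params.nucleus_radius_nm + 2 * p)
    n_px = int(math.ceil(extent / p))
    idx = (np.arange(n_px) + 0.5) * p
    xx, yy = np.meshgrid(idx, idx)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    nucleus = r2 <= params.nucleus_radius_nm**2
    foci = np.zeros_like(nucleus)
    for cx, cy in focus_centers:
        foci |= (xx - cx) ** 2 + (yy - cy) ** 2 <= params.foci_mask_radius_nm**2
    foci &= nucleus  # guarantee foci mask subset of nucleus mask
    return (
        BinaryMask(nucleus, p, kind="nucleus"),
        BinaryMask(foci, p, kind="foci"),
    )


def _uniform_in_disc(rng, n, center, radius):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _place_foci(rng, params: SceneParams, center) -> np.ndarray:
    min_sep = 4.0 * params.focus_sigma_nm
    if params.n_foci == 0:
        return np.zeros((0, 2))
    for _ in range(10_000):
        centers = _uniform_in_disc(rng, params.n_foci, center, params.nucleus_radius_nm)
        if params.n_foci == 1:
            return centers
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        if d[np.triu_indices(params.n_foci, 1)].min() >= min_sep:
            return centers
    raise PlacementError(
        f"could not place {params.n_foci} foci with separation >= {min_sep:.0f} nm "
        f"in a nucleus of radius {params.nucleus_radius_nm:.0f} nm"
    )


def _sample_into_mask(rng, mask: BinaryMask, draw, n, max_rounds=1000):
    """Draw n points via ``draw(rng, m)``, rejection-resampling outside the mask."""
    out = np.empty((n, 2))
    todo = n
    filled = 0
    for _ in range(max_rounds):
        if todo == 0:
            return out
        pts = draw(rng, todo)
        ok = mask.contains(pts[:, 0], pts[:, 1])
        k = int(ok.sum())
        out[filled : filled + k] = pts[ok]
        filled += k
        todo -= k
    raise RuntimeError("rejection sampling failed to fill the mask")


def generate_scene(params: SceneParams) -> GroundTruthScene:
    """Realize a scene: focus placement, focus/background true positions.

    Deterministic given ``params.seed``.  Focus centers are uniform in the
    nucleus disc with pairwise separation >= 4*focus_sigma; all true
    positions are rejection-sampled into the rasterized nucleus mask.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    margin = 2 * params.mask_pixel_nm
    center = (params.nucleus_radius_nm + margin, params.nucleus_radius_nm + margin)
    focus_centers = _place_foci(rng, params, center)
    nucleus_mask, foci_mask = _build_masks(params, center, focus_centers)
    area_um2 = mask_area(nucleus_mask)

    def channel_positions(events_per_focus, bg_density):
        pos, lab = [], []
        for k, fc in enumerate(focus_centers):
            draw = lambda r, m: fc + r.normal(0.0, params.focus_sigma_nm, (m, 2))
            p = _sample_into_mask(rng, nucleus_mask, draw, events_per_focus)
            pos.append(p)
            lab.append(np.full(events_per_focus, k))
        n_bg = int(rng.poisson(bg_density * area_um2))
        draw_bg = lambda r, m: _uniform_in_disc(r, m, center, params.nucleus_radius_nm)
        pos.append(_sample_into_mask(rng, nucleus_mask, draw_bg, n_bg))
        lab.append(np.full(n_bg, -1))
        return np.concatenate(pos) if pos else np.zeros((0, 2)), np.concatenate(lab)

    pos1, lab1 = channel_positions(params.events_per_focus_ch1, params.background_density_ch1)

    # channel 2: per-focus events, an anchored subset tied to channel-1 events
    pos2_parts, lab2_parts, anch_parts, aidx_parts = [], [], [], []
    for k, fc in enumerate(focus_centers):
        n2 = params.events_per_focus_ch2
        ch1_rows = np.flatnonzero(lab1 == k)
        anchored = rng.random(n2) < params.coloc_fraction
        if len(ch1_rows) == 0:
            anchored[:] = False
        p = np.empty((n2, 2))
        aidx = np.full(n2, -1)
        n_anch = int(anchored.sum())
        if n_anch:
            chosen = rng.choice(ch1_rows, size=n_anch)
            aidx[anchored] = chosen
            draw_pairs = pos1[chosen] + rng.normal(
                0.0, params.coloc_displacement_sigma_nm, (n_anch, 2)
            )
            # re-anchor any that fell outside the nucleus
            bad = ~nucleus_mask.contains(draw_pairs[:, 0], draw_pairs[:, 1])
            while bad.any():
                draw_pairs[bad] = pos1[chosen[bad]] + rng.normal(
                    0.0, params.coloc_displacement_sigma_nm, (int(bad.sum()), 2)
                )
                bad = ~nucleus_mask.contains(draw_pairs[:, 0], draw_pairs[:, 1])
            p[anchored] = draw_pairs
        n_free = n2 - n_anch
        if n_free:
            draw = lambda r, m: fc + r.normal(0.0, params.sigma_ch2_nm, (m, 2))
            p[~anchored] = _sample_into_mask(rng, nucleus_mask, draw, n_free)
        pos2_parts.append(p)
        lab2_parts.append(np.full(n2, k))
        anch_parts.append(anchored)
        aidx_parts.append(aidx)
    n_bg2 = int(rng.poisson(params.background_density_ch2 * area_um2))
    draw_bg = lambda r, m: _uniform_in_disc(r, m, center, params.nucleus_radius_nm)
    pos2_parts.append(_sample_into_mask(rng, nucleus_mask, draw_bg, n_bg2))
    lab2_parts.append(np.full(n_bg2, -1))
    anch_parts.append(np.zeros(n_bg2, dtype=bool))
    aidx_parts.append(np.full(n_bg2, -1))

    return GroundTruthScene(
        params=params,
        center_nm=center,
        focus_centers=focus_centers,
        positions_ch1=pos1,
        labels_ch1=lab1.astype(int),
        positions_ch2=np.concatenate(pos2_parts) if pos2_parts else np.zeros((0, 2)),
        labels_ch2=np.concatenate(lab2_parts).astype(int),
        anchored_ch2=np.concatenate(anch_parts).astype(bool),
        anchor_index_ch2=np.concatenate(aidx_parts).astype(int),
        nucleus_mask=nucleus_mask,
        foci_mask=foci_mask,
    )


def sample_localizations(
    scene: GroundTruthScene,
    channel: int,
    mean_blinks_per_emitter: float = 1.0,
    blink_distribution: str = "geometric",
    amplitude_mean: float = 1000.0,
    amplitude_sigma: float = 0.5,
) -> OrteMatrix:
    """Emit blink events from true positions into an orte matrix.

    Each emitter blinks a geometric (support >= 1, default) or Poisson
    number of times; every blink is the true position plus isotropic
    Gaussian noise with the channel's localization error, which is also
    recorded in the ``loc_error_nm`` column.  Amplitudes are log-normal.
    Deterministic given the scene's seed and channel.
    """
    if channel not in (1, 2):
        raise ValueError("channel must be 1 or 2")
    if mean_blinks_per_emitter < 1:
        raise ValueError("mean_blinks_per_emitter must be >= 1")
    params = scene.params
    rng = np.random.default_rng([params.seed, 7919, channel])
    positions = scene.positions(channel)
    loc_error = params.loc_error_ch1_nm if channel == 1 else params.loc_error_ch2_nm

    n = len(positions)
    if blink_distribution == "geometric":
        blinks = rng.geometric(1.0 / mean_blinks_per_emitter, n) if n else np.zeros(0, int)
    elif blink_distribution == "poisson":
        blinks = rng.poisson(mean_blinks_per_emitter, n) if n else np.zeros(0, int)
    else:
        raise ValueError("blink_distribution must be 'geometric' or 'poisson'")

    rep = np.repeat(np.arange(n), blinks)
    xy = positions[rep]
    if loc_error > 0 and len(xy):
        xy = xy + rng.normal(0.0, loc_error, xy.shape)
    amps = rng.lognormal(np.log(amplitude_mean), amplitude_sigma, len(xy))
    data = pd.DataFrame(
        {
            "amplitude": amps,
            "x_nm": xy[:, 0] if len(xy) else np.zeros(0),
            "y_nm": xy[:, 1] if len(xy) else np.zeros(0),
            "loc_error_nm": np.full(len(xy), float(loc_error)),
            "emitter": rep,
        }
    )
    return OrteMatrix(data, channel=f"ch{channel}", source=f"synthetic(seed={params.seed})")


def render_frames(
    scene: GroundTruthScene,
    n_frames: int = 2000,
    pixel_size_nm: float = 100.0,
    psf_sigma_nm: float = 150.0,
    photons_per_blink: float = 1000.0,
    background_photons: float = 10.0,
    seed: int = 0,
    channel: int = 1,
    positions: np.ndarray | None = None,
    poisson_noise: bool = True,
    fov_nm: float | None = None,
) -> FrameStack:
    """Render blink events into a Poisson-noised multi-frame image stack.

    Every true position (or row of ``positions`` if given) produces exactly
    one blink, assigned to a uniformly random frame.  Each spot is an
    integrated 2D Gaussian (per-pixel erf quadrature); spots outside the
    field of view are clipped with a logged warning.  The realized
    blink-to-frame assignment is attached as ``FrameStack.ground_truth``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng([seed, 104729])
    pts = np.asarray(positions if positions is not None else scene.positions(channel), float)
    extent = fov_nm or 2.0 * (scene.params.nucleus_radius_nm + 2 * scene.params.mask_pixel_nm)
    n_px = int(math.ceil(extent / pixel_size_nm))
    frames = np.zeros((n_frames, n_px, n_px))

    frame_of = rng.integers(0, n_frames, len(pts))
    n_clipped = 0
    from scipy.special import erf

    sig = psf_sigma_nm / pixel_size_nm
    half = int(math.ceil(5 * sig))
    for (x, y), f in zip(pts, frame_of):
        cx, cy = x / pixel_size_nm, y / pixel_size_nm
        if not (0 <= cx < n_px and 0 <= cy < n_px):
            n_clipped += 1
            continue
        j0, j1 = max(0, int(cx) - half), min(n_px, int(cx) + half + 1)
        i0, i1 = max(0, int(cy) - half), min(n_px, int(cy) + half + 1)
        ex = 0.5 * (
            erf((np.arange(j0, j1 + 1) - cx) / (sig * math.sqrt(2)))
        )
        ey = 0.5 * (
            erf((np.arange(i0, i1 + 1) - cy) / (sig * math.sqrt(2)))
        )
        frames[f, i0:i1, j0:j1] += photons_per_blink * np.outer(np.diff(ey), np.diff(ex))
    if n_clipped:
        logger.warning("render_frames: %d blink(s) outside the field of view clipped", n_clipped)

    frames += background_photons
    if poisson_noise:
        frames = rng.poisson(frames).astype(np.uint16)
    gt = pd.DataFrame(
        {"blink": np.arange(len(pts)), "frame": frame_of, "x_nm": pts[:, 0], "y_nm": pts[:, 1]}
    )
    return FrameStack(frames, pixel_size_nm, ground_truth=gt)


def write_scene(scene: GroundTruthScene, outdir) -> None:
    """Serialize a scene: JSON params/centers, TSV positions, TIFF masks."""
    from .io_masks import write_mask

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "scene.json", "w") as fh:
        json.dump(
            {
                "params": asdict(scene.params),
                "center_nm": list(scene.center_nm),
                "focus_centers_nm": scene.focus_centers.tolist(),
            },
            fh,
            indent=1,
        )
    for ch in (1, 2):
        df = pd.DataFrame(scene.positions(ch), columns=["x_nm", "y_nm"])
        df["label"] = scene.labels(ch)
        df.to_csv(outdir / f"true_positions_ch{ch}.tsv", sep="\t", index=False)
    write_mask(scene.nucleus_mask, outdir / "nucleus_mask.tif")
    write_mask(scene.foci_mask, outdir / "foci_mask.tif")
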