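"""Rendering of synthetic replica micrographs with ground truth.

A scene renders to an 8-bit grayscale image emulating a platinum/carbon
replica viewed in transmission EM: a mid-gray textured background, IMPs
as unidirectionally shadowed bumps (a bright highlight toward the
platinum source paired with a dark shadow behind, as produced by 60
degree unidirectional shadowing), and colloidal gold as near-black
anti-aliased disks whose diameter encodes the size class (5 or 10 nm).
The ground-truth table lists every particle's center in nm with its
class and channel, so detector performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SynapseScene

BACKGROUND_GRAY = 128.0
GOLD_GRAY = 12.0
DEFAULT_NOISE_SIGMA = 8.0
DEFAULT_PX_SIZE_NM = 0.5
IMP_RADIUS_NM = 4.0
IMP_AMPLITUDE = 26.0
TEXTURE_AMPLITUDE = 5.0
TEXTURE_SCALE_NM = 6.0
MAX_CANVAS_PX = 4096


class RenderError(RuntimeError):
    """Raised when a scene does not fit the rendering canvas."""


@dataclass
class Rendering:
    """A rendered micrograph plus its calibration and ground truth."""

    image: np.ndarray  # uint8, (H, W)
    px_size: float  # nm/px
    origin: tuple[float, float]  # nm coords of the (0, 0) pixel corner
    truth: pd.DataFrame  # x_nm, y_nm, channel, size_class_nm, face

    def to_pixel(self, x_nm: np.ndarray, y_nm: np.ndarray):
        """nm -> fractional pixel coordinates (col, row)."""
        return (
            (np.asarray(x_nm) - self.origin[0]) / self.px_size,
            (np.asarray(y_nm) - self.origin[1]) / self.px_size,
        )


def _stamp_disk(img: np.ndarray, cx: float, cy: float, radius_px: float, value: float):
    """Alpha-composite an anti-aliased disk; coordinates in pixels."""
    r_int = int(np.ceil(radius_px + 1.5))
    x0, x1 = int(np.floor(cx)) - r_int, int(np.floor(cx)) + r_int + 1
    y0, y1 = int(np.floor(cy)) - r_int, int(np.floor(cy)) + r_int + 1
    x0c, x1c = max(x0, 0), min(x1, img.shape[1])
    y0c, y1c = max(y0, 0), min(y1, img.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
    # pixel centers at integer + 0.5
    d = np.hypot(xs + 0.5 - cx, ys + 0.5 - cy)
    cov = np.clip(radius_px + 0.5 - d, 0.0, 1.0)
    patch = img[y0c:y1c, x0c:x1c]
    patch *= 1.0 - cov
    patch += value * cov


def _stamp_gaussian(img: np.ndarray, cx: float, cy: float, sigma_px: float, amp: float):
    r_int = int(np.ceil(3 * sigma_px))
    x0c, x1c = max(int(cx) - r_int, 0), min(int(cx) + r_int + 1, img.shape[1])
    y0c, y1c = max(int(cy) - r_int, 0), min(int(cy) + r_int + 1, img.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
    g = amp * np.exp(
        -((xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2) / (2 * sigma_px**2)
    )
    img[y0c:y1c, x0c:x1c] += g


def render_image(
    scene: SynapseScene,
    px_size: float = DEFAULT_PX_SIZE_NM,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    rng: np.random.Generator | int | None = None,
    shading_direction_deg: float = 30.0,
    margin_nm: float = 60.0,
) -> Rendering:
    """Render a scene to an 8-bit micrograph with its ground-truth table.

    ``px_size`` must lie in [0.25, 2] nm/px.  Noise is additive Gaussian
    in gray levels (sigma = ``noise_sigma``), seeded from ``rng``.
    """
    if not (0.25 <= px_size <= 2.0):
        raise ValueError(f"px_size must be in [0.25, 2] nm/px, got {px_size}")
    rng = np.random.default_rng(rng)

    xs_all = [scene.imp_points[:, 0]] if len(scene.imp_points) else []
    ys_all = [scene.imp_points[:, 1]] if len(scene.imp_points) else []
    if scene.particles:
        pxy = np.array([[p.position.x, p.position.y] for p in scene.particles])
        xs_all.append(pxy[:, 0])
        ys_all.append(pxy[:, 1])
    if scene.pface_region is not None and not scene.pface_region.is_empty:
        bx = scene.pface_region.bounds
        xs_all.append(np.array([bx[0], bx[2]]))
        ys_all.append(np.array([bx[1], bx[3]]))
    if not xs_all:
        raise RenderError("empty scene: nothing to render")
    x_min = float(min(a.min() for a in xs_all)) - margin_nm
    x_max = float(max(a.max() for a in xs_all)) + margin_nm
    y_min = float(min(a.min() for a in ys_all)) - margin_nm
    y_max = float(max(a.max() for a in ys_all)) + margin_nm
    width = int(np.ceil((x_max - x_min) / px_size))
    height = int(np.ceil((y_max - y_min) / px_size))
    if width > MAX_CANVAS_PX or height > MAX_CANVAS_PX:
        raise RenderError(
            f"scene needs a {width}x{height} px canvas, exceeding {MAX_CANVAS_PX}"
        )

    img = np.full((height, width), BACKGROUND_GRAY, dtype=float)

    # replica texture: band-limited noise
    from scipy.ndimage import gaussian_filter

    tex = rng.standard_normal((height, width))
    tex = gaussian_filter(tex, TEXTURE_SCALE_NM / px_size)
    sd = tex.std()
    if sd > 0:
        img += TEXTURE_AMPLITUDE * tex / sd

    # IMPs: shadowed bumps (highlight toward the metal source, shadow behind)
    th = np.deg2rad(shading_direction_deg)
    ux, uy = np.cos(th), np.sin(th)
    sigma_imp = IMP_RADIUS_NM / px_size
    off = 0.8 * sigma_imp
    for x, y in np.asarray(scene.imp_points, dtype=float):
        cx, cy = (x - x_min) / px_size, (y - y_min) / px_size
        _stamp_gaussian(img, cx - ux * off, cy - uy * off, sigma_imp, IMP_AMPLITUDE)
        _stamp_gaussian(img, cx + ux * off, cy + uy * off, sigma_imp, -IMP_AMPLITUDE)

    # gold: near-black anti-aliased disks
    truth_rows = []
    for p in scene.particles:
        cx, cy = (p.position.x - x_min) / px_size, (p.position.y - y_min) / px_size
        _stamp_disk(img, cx, cy, p.size_class / (2 * px_size), GOLD_GRAY)
        truth_rows.append(
            dict(
                x_nm=p.position.x,
                y_nm=p.position.y,
                channel=p.channel,
                size_class_nm=p.size_class,
                face=p.face,
            )
        )

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        truth_rows, columns=["x_nm", "y_nm", "channel", "size_class_nm", "face"]
    )
    return Rendering(image=img, px_size=px_size, origin=(x_min, y_min), truth=truth)
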