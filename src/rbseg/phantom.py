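"""Seeded synthetic fundus phantoms with paired tumor / optic-disc masks.

Real retinoblastoma fundus photographs are not publicly distributable, so the
generator renders the imaging traits the segmentation method relies on: a warm
orange-red retinal background with a gentle radial brightness gradient, dark
vessel curves radiating from a bright roughly-circular optic disc, zero or
more whitish blurred-edge tumor blobs (the leukocoric appearance of
retinoblastoma), a peripheral vignette, and pixel noise.  Every phantom
carries ground-truth binary masks for the tumors and the disc, recorded from
the pre-blur supports.

Geometry parameters are expressed in pixels at the reference 320 x 480
resolution and are rescaled proportionally when a different output shape is
requested, so a half-resolution phantom is a shrunken version of the same
scene statistics.

Emulated deliberately:
  * the intensity ordering background < tumor < disc, which makes the disc
    the method's classic false positive;
  * tumors dimmer than the disc but well above background, with blurred
    margins (partial-volume pixels);
  * thin dark vessels that post-processing must suppress;
  * wide-field, frame-filling acquisition: the vignette darkens only the far
    corners by default (a hard black border appears when ``vignette_radius``
    is reduced).

Not emulated: photorealistic texture, regression patterns, calcification,
vitreous seeding, illumination artifacts.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

REFERENCE_SHAPE = (320, 480)

# scene palette (RGB, [0,1]); grayscale lumas: bg ~0.51, vessel ~0.23, disc ~0.94
_BG_COLOR = np.array([0.80, 0.42, 0.20])
_VESSEL_FACTOR = 0.45
_CAPILLARY_FACTOR = 0.75  # fine dark mesh, luma ~0.38
_SPECKLE_LIFT = 0.12  # drusen-like bright dots, luma ~0.62
_DISC_COLOR = np.array([1.00, 0.95, 0.75])
_TUMOR_COLOR = np.array([1.05, 0.97, 0.85])  # luma ~= 1: gray lift == brightness


@dataclass(frozen=True)
class PhantomParams:
    """Scene statistics of a phantom (pixel units at 320 x 480)."""

    tumor_count_range: tuple[int, int] = (1, 3)
    tumor_radius_range: tuple[float, float] = (14.0, 42.0)
    tumor_brightness: float = 0.28
    disc_radius_range: tuple[float, float] = (18.0, 30.0)
    vessel_count: int = 6
    noise_sigma: float = 0.03
    vignette_radius: float = 250.0
    edge_blur_sigma: float = 1.5

    def __post_init__(self) -> None:
        for name in ("tumor_count_range", "tumor_radius_range", "disc_radius_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Phantom:
    """A rendered scene with its ground truth."""

    rgb: np.ndarray  # (H, W, 3) in [0,1]
    tumor_mask: np.ndarray  # (H, W) bool
    disc_mask: np.ndarray  # (H, W) bool
    seed: int

    @property
    def is_healthy(self) -> bool:
        return not self.tumor_mask.any()


def _ellipse_support(
    shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float], angle: float
) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _draw_vessels(
    shape: tuple[int, int],
    rng: np.random.Generator,
    origin: tuple[float, float],
    count: int,
    width: float,
) -> np.ndarray:
    """Dark vessel support: random walks radiating from the disc."""
    H, W = shape
    support = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    r = max(1.0, width)
    for _ in range(count):
        ang = rng.uniform(0, 2 * np.pi)
        y, x = origin
        step = max(2.0, 0.012 * W)
        n_steps = int(rng.integers(int(0.4 * W / step), int(1.0 * W / step)))
        for _ in range(n_steps):
            y += step * np.sin(ang)
            x += step * np.cos(ang)
            ang += rng.normal(0, 0.35)
            if not (0 <= y < H and 0 <= x < W):
                break
            y0, y1 = int(max(0, y - r - 1)), int(min(H, y + r + 2))
            x0, x1 = int(max(0, x - r - 1)), int(min(W, x + r + 2))
            patch = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2 <= r * r
            support[y0:y1, x0:x1] |= patch
    return support


def _draw_speckle(
    shape: tuple[int, int], rng: np.random.Generator, density: float, radius: float
) -> np.ndarray:
    """Scattered bright dots (drusen-like); support fraction ~ density."""
    H, W = shape
    r = max(1.0, radius)
    n_dots = int(density * H * W / (np.pi * r * r))
    support = np.zeros(shape, dtype=bool)
    ys = rng.uniform(0, H, size=n_dots)
    xs = rng.uniform(0, W, size=n_dots)
    for y, x in zip(ys, xs):
        y0, y1 = int(max(0, y - r)), int(min(H, y + r + 1))
        x0, x1 = int(max(0, x - r)), int(min(W, x + r + 1))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        support[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    return support.astype(float)


def generate_phantom(
    seed: int,
    params: PhantomParams | None = None,
    shape: tuple[int, int] = REFERENCE_SHAPE,
) -> Phantom:
    """Render one phantom; bit-identical for equal ``(seed, params, shape)``.

    Layer order: background gradient, vessels, optic disc, tumor blobs,
    vignette, additive Gaussian noise clipped to [0, 1].  Tumor placement is
    rejection-sampled to avoid the disc (bounded retries, then an error), so
    the two ground-truth masks are always disjoint.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    H, W = shape
    if H < 8 or W < 8:
        raise ValueError("phantom shape is too small")
    sc = H / REFERENCE_SHAPE[0]  # geometric scale factor

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    # normalized elliptical radius: 1.0 at the mid-edges, sqrt(2) at corners
    rho = np.sqrt(((yy - cy) / (H / 2)) ** 2 + ((xx - cx) / (W / 2)) ** 2)

    # background: warm color with a gentle radial brightness falloff.  The
    # falloff and mottle amplitudes stay well below the pixel noise so the
    # healthy background remains a single near-Gaussian intensity mode.
    shade = 1.0 - 0.03 * rho**2 + rng.normal(0, 0.01)
    rgb = _BG_COLOR[None, None, :] * shade[:, :, None]
    # low-frequency mottling so the background is not perfectly flat
    mottle = gaussian_filter(rng.normal(0, 1.0, size=shape), sigma=18 * sc)
    mottle /= max(np.abs(mottle).max(), 1e-9)
    rgb *= (1.0 + 0.015 * mottle)[:, :, None]

    # optic disc: bright ellipse, eccentric along the horizontal axis
    disc_r = rng.uniform(*params.disc_radius_range) * sc
    side = rng.choice([-1.0, 1.0])
    disc_c = (
        cy + rng.uniform(-0.18, 0.18) * H,
        cx + side * rng.uniform(0.22, 0.34) * W,
    )
    disc_mask = _ellipse_support(
        shape, disc_c, (disc_r * rng.uniform(0.9, 1.1), disc_r), rng.uniform(0, np.pi)
    )

    vessels = _draw_vessels(
        shape, rng, disc_c, params.vessel_count, width=1.2 * sc
    )
    vessel_soft = gaussian_filter(vessels.astype(float), sigma=0.6 * sc)
    rgb *= (1.0 - (1.0 - _VESSEL_FACTOR) * np.clip(vessel_soft, 0, 1))[:, :, None]

    # fine retinal texture: a thin dark capillary mesh and bright drusen-like
    # speckle.  Both are sub-median-filter-width structures with their own
    # intensity modes, the texture the morphological cleanup exists to remove.
    # stroke width saturates at 1 px below the reference resolution, so the
    # stroke count scales with the linear factor to keep the mesh spacing
    # (in pixels) compatible with the median-filter window
    capillaries = _draw_vessels(
        shape, rng, (cy, cx), count=max(4, round(8 * params.vessel_count * sc)),
        width=0.6 * sc,
    )
    rgb *= (1.0 - (1.0 - _CAPILLARY_FACTOR) * capillaries)[:, :, None]
    speckle = _draw_speckle(shape, rng, density=0.02, radius=1.1 * sc)
    rgb += (_SPECKLE_LIFT * speckle)[:, :, None] * _TUMOR_COLOR

    disc_soft = gaussian_filter(disc_mask.astype(float), sigma=0.35 * params.edge_blur_sigma * sc)
    rgb = rgb * (1 - disc_soft[:, :, None]) + disc_soft[:, :, None] * _DISC_COLOR

    # tumors: unions of overlapping ellipses, blurred margins, avoiding the disc
    n_tumors = int(rng.integers(params.tumor_count_range[0], params.tumor_count_range[1] + 1))
    tumor_mask = np.zeros(shape, dtype=bool)
    for _ in range(n_tumors):
        blob = _place_tumor(shape, rng, params, sc, disc_mask, rho)
        tumor_mask |= blob
    if tumor_mask.any():
        tumor_soft = gaussian_filter(
            tumor_mask.astype(float), sigma=params.edge_blur_sigma * sc
        )
        rgb = rgb + (params.tumor_brightness * tumor_soft)[:, :, None] * _TUMOR_COLOR

    # vignette: cosine falloff to black beyond vignette_radius
    v_r = params.vignette_radius * sc / (H / 2)  # in rho units
    t = np.clip((rho - 0.85 * v_r) / (0.30 * v_r), 0.0, 1.0)
    rgb *= (0.5 * (1 + np.cos(np.pi * t)))[:, :, None]

    if params.noise_sigma > 0:
        rgb = rgb + rng.normal(0, params.noise_sigma, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    tumor_mask &= ~disc_mask  # defensive; placement already avoids the disc
    return Phantom(rgb=rgb, tumor_mask=tumor_mask, disc_mask=disc_mask, seed=seed)


def _place_tumor(
    shape: tuple[int, int],
    rng: np.random.Generator,
    params: PhantomParams,
    sc: float,
    disc_mask: np.ndarray,
    rho: np.ndarray,
    max_retries: int = 40,
) -> np.ndarray:
    H, W = shape
    r_lo, r_hi = params.tumor_radius_range
    for _ in range(max_retries):
        r = rng.uniform(r_lo, r_hi) * sc
        if 2 * r > min(H, W):
            continue  # larger than the field: re-draw
        c = (rng.uniform(0.12 * H, 0.88 * H), rng.uniform(0.10 * W, 0.90 * W))
        if rho[int(c[0]), int(c[1])] > 0.95:  # keep the core inside the field
            continue
        blob = np.zeros(shape, dtype=bool)
        n_lobes = int(rng.integers(2, 5))
        for _ in range(n_lobes):
            off = rng.normal(0, 0.35 * r, size=2)
            radii = (r * rng.uniform(0.55, 1.0), r * rng.uniform(0.55, 1.0))
            blob |= _ellipse_support(shape, (c[0] + off[0], c[1] + off[1]), radii, rng.uniform(0, np.pi))
        if not (blob & disc_mask).any():
            return blob
    raise RuntimeError("could not place a tumor clear of the optic disc")


@dataclass
class DatasetItem:
    name: str
    seed: int
    healthy: bool


def generate_dataset(
    n: int,
    seed: int,
    params: PhantomParams | None = None,
    healthy_fraction: float = 0.0,
    shape: tuple[int, int] = REFERENCE_SHAPE,
) -> tuple[list[Phantom], list[DatasetItem]]:
    """Seeded dataset of phantoms; item ``i`` uses seed ``seed + i``.

    Exactly ``round(healthy_fraction * n)`` items are rendered tumor-free;
    their positions within the dataset are a seeded permutation so healthy and
    diseased cases interleave the way a clinic's image stream would.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= healthy_fraction <= 1.0:
        raise ValueError("healthy_fraction must lie in [0, 1]")
    params = params or PhantomParams()
    n_healthy = int(round(healthy_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:n_healthy] = True
    np.random.default_rng(seed).shuffle(flags)

    healthy_params = replace(params, tumor_count_range=(0, 0))
    phantoms, manifest = [], []
    for i in range(n):
        p = healthy_params if flags[i] else params
        ph = generate_phantom(seed + i, p, shape=shape)
        phantoms.append(ph)
        manifest.append(
            DatasetItem(name=f"phantom_{i:05d}", seed=seed + i, healthy=bool(flags[i]))
        )
    return phantoms, manifest


def healthy_references(
    seed: int,
    params: PhantomParams | None = None,
    shape: tuple[int, int] = REFERENCE_SHAPE,
) -> list[np.ndarray]:
    """Three tumor-free grayscale phantoms standing in for the healthy set."""
    from .pseudolabel import standardize_image

    params = replace(params or PhantomParams(), tumor_count_range=(0, 0))
    refs = []
    for i in range(3):
        ph = generate_phantom(seed + 10_000 + i, params, shape=shape)
        refs.append(standardize_image(ph.rgb, shape=shape))
    return refs


def write_dataset(
    out_dir: str | Path,
    phantoms: list[Phantom],
    manifest: list[DatasetItem],
) -> Path:
    """Write images, masks and a CSV manifest under ``out_dir``."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "tumor_masks").mkdir(exist_ok=True)
    (out / "disc_masks").mkdir(exist_ok=True)
    for ph, item in zip(phantoms, manifest):
        iio.imwrite(out / "images" / f"{item.name}.png", (ph.rgb * 255).round().astype(np.uint8))
        iio.imwrite(out / "tumor_masks" / f"{item.name}.png", ph.tumor_mask.astype(np.uint8) * 255)
        iio.imwrite(out / "disc_masks" / f"{item.name}.png", ph.disc_mask.astype(np.uint8) * 255)
    manifest_path = out / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "seed", "healthy"])
        for item in manifest:
            writer.writerow([item.name, item.seed, int(item.healthy)])
    logger.info("wrote %d phantoms to %s", len(phantoms), out)
    return manifest_path
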