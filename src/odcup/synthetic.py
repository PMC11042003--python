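"""Synthetic fundus phantoms with paired ground truth.

Real fundus photographs show a reddish retina, a bright roughly elliptical
optic disc, a brighter cup depression nested inside it and offset to one
side, and dark vessels that bend as they cross the disc rim. The phantom
generator reproduces exactly those geometric and photometric cues — enough
for the preprocessing, training and evaluation pipeline to be exercised
end-to-end — without attempting photorealism or pathology.

Every phantom is fully determined by ``(spec.seed, index)``. Ground truth
is authored as 64-vertex boundary polygons of the two ellipses; the label
planes are rasterized from those same polygons, so annotations and masks
are consistent by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import gaussian

from .preprocess import (BoundaryAnnotation, boundary_to_mask,
                         build_label_volume, save_image, save_mask,
                         write_boundary_file)

N_POLY_VERTICES = 64
# cup/disc ratio is drawn this far inside cup_ratio_range so the rasterized
# vertical extents still land inside the declared range (~1 px quantization
# on a >= 30 px cup diameter)
RATIO_MARGIN = 0.03
ECC_RANGE = (0.8, 1.25)  # horizontal/vertical semi-axis ratio (<= 1.3)
EDGE_MARGIN = 2.0  # px between the disc ellipse and the image border


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters governing phantom generation.

    Ranges are inclusive; ``disc_radius_range`` is a fraction of the
    shorter image side (the vertical semi-axis), ``cup_ratio_range`` the
    cup/disc radius ratio, which is also the vertical cup-to-disc ratio of
    the ground truth.
    """

    n_images: int = 1
    height_range: tuple[int, int] = (96, 160)
    width_range: tuple[int, int] = (96, 160)
    disc_radius_range: tuple[float, float] = (0.18, 0.30)
    cup_ratio_range: tuple[float, float] = (0.30, 0.70)
    n_vessels: int = 4
    noise_sigma: float = 0.02
    illumination_strength: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.cup_ratio_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("cup_ratio_range must lie strictly inside (0, 1)")
        if hi - lo < 2 * RATIO_MARGIN:
            raise ValueError("cup_ratio_range is too narrow")
        for name in ("height_range", "width_range"):
            a, b = getattr(self, name)
            if a < 16 or b < a:
                raise ValueError(f"{name} must satisfy 16 <= lo <= hi")
        rlo, rhi = self.disc_radius_range
        if not (0.0 < rlo <= rhi):
            raise ValueError("disc_radius_range must be positive")
        min_side = min(self.height_range[0], self.width_range[0])
        max_semi = rhi * ECC_RANGE[1] * min_side + EDGE_MARGIN
        if 2 * max_semi >= min_side:
            raise ValueError(
                "infeasible geometry: the disc cannot fit inside the smallest image"
            )
        if self.n_vessels < 0 or self.noise_sigma < 0 or self.illumination_strength < 0:
            raise ValueError("n_vessels, noise_sigma, illumination_strength must be >= 0")


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, N_POLY_VERTICES, endpoint=False)
    return np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])


def generate_phantom(spec: PhantomSpec, index: int):
    """Draw one phantom; returns (pixels, LabelVolume, disc_ann, cup_ann)."""
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))

    h = int(rng.integers(spec.height_range[0], spec.height_range[1] + 1))
    w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
    min_side = min(h, w)

    # disc geometry: vertical semi-axis ry, mildly eccentric horizontally
    ry = rng.uniform(*spec.disc_radius_range) * min_side
    rx = ry * rng.uniform(*ECC_RANGE)
    if 2 * (rx + EDGE_MARGIN) >= w or 2 * (ry + EDGE_MARGIN) >= h:
        raise ValueError("infeasible geometry: disc does not fit in the drawn image")
    cx = rng.uniform(rx + EDGE_MARGIN, w - 1 - rx - EDGE_MARGIN)
    cy = rng.uniform(ry + EDGE_MARGIN, h - 1 - ry - EDGE_MARGIN)

    # cup: same shape scaled by rho, offset toward one side but kept
    # strictly inside the disc with >= 1 px slack
    rho = rng.uniform(spec.cup_ratio_range[0] + RATIO_MARGIN,
                      spec.cup_ratio_range[1] - RATIO_MARGIN)
    crx, cry = rho * rx, rho * ry
    max_dx = max(rx - crx - 1.0, 0.0)
    dx = rng.uniform(0.25, 0.75) * max_dx * rng.choice([-1.0, 1.0])
    dy = rng.uniform(-0.2, 0.2) * max(ry - cry - 1.0, 0.0)

    disc_ann = BoundaryAnnotation("disc", _ellipse_polygon(cx, cy, rx, ry))
    cup_ann = BoundaryAnnotation("cup", _ellipse_polygon(cx + dx, cy + dy, crx, cry))
    disc_mask = boundary_to_mask(disc_ann, h, w)
    cup_mask = boundary_to_mask(cup_ann, h, w)
    vol = build_label_volume(disc_mask, cup_mask)

    # -- render ---------------------------------------------------------
    img = np.empty((h, w, 3))
    img[:] = (0.46, 0.20, 0.12)  # reddish retina base

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    gx = rng.uniform(0.25, 0.75) * w
    gy = rng.uniform(0.25, 0.75) * h
    d = np.hypot(xx - gx, yy - gy)
    illum = 1.0 + spec.illumination_strength * (0.5 - d / d.max())
    img *= illum[..., None]

    img[disc_mask == 1] = (0.88, 0.72, 0.42)
    img[cup_mask == 1] = (0.98, 0.90, 0.62)

    _draw_vessels(img, rng, spec.n_vessels, cx, cy, rx, ry, h, w, cup_mask)

    img = gaussian(img, sigma=0.8, channel_axis=-1, preserve_range=True)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img, vol, disc_ann, cup_ann


def _draw_vessels(img: np.ndarray, rng: np.random.Generator, n_vessels: int,
                  cx: float, cy: float, rx: float, ry: float, h: int, w: int,
                  cup_mask: np.ndarray) -> None:
    """Dark quadratic-Bezier strokes running across the disc.

    The control point sits inside the disc, so the curves bend at the rim;
    strokes are occluded over the cup (they vanish at the cup boundary),
    which keeps the cup the brightest region and gives the segmenter the
    clinically salient vessel-kink cue exactly at the rim.
    """
    color = np.array([0.30, 0.08, 0.06])
    half = max(1, round(min(h, w) / 110))
    canvas = np.zeros((h, w), dtype=bool)
    for _ in range(n_vessels):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        reach = max(h, w)
        p0 = np.array([cx + reach * np.cos(angle), cy + reach * np.sin(angle)])
        p2 = np.array([cx - reach * np.cos(angle), cy - reach * np.sin(angle)])
        p1 = np.array([cx + rng.uniform(-0.8, 0.8) * rx,
                       cy + rng.uniform(-0.8, 0.8) * ry])
        t = np.linspace(0.0, 1.0, 4 * reach)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        pts = np.unique(pts.round().astype(int), axis=0)
        for px, py in pts:
            if -half <= px < w + half and -half <= py < h + half:
                canvas[max(py - half, 0):py + half + 1,
                       max(px - half, 0):px + half + 1] = True
    img[canvas & (cup_mask == 0)] = color


def generate_dataset(spec: PhantomSpec, out_dir) -> Path:
    """Write ``spec.n_images`` phantoms plus a manifest CSV to ``out_dir``.

    Layout: ``image_###.png``, ``disc_###.txt`` / ``cup_###.txt`` boundary
    files, ``disc_###.png`` / ``cup_###.png`` 0/255 masks and
    ``manifest.csv`` with the training-manifest columns (paths relative to
    the manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_images):
        img, vol, disc_ann, cup_ann = generate_phantom(spec, i)
        names = {
            "image_path": f"image_{i:03d}.png",
            "disc_ann_path": f"disc_{i:03d}.txt",
            "cup_ann_path": f"cup_{i:03d}.txt",
            "disc_mask_path": f"disc_{i:03d}.png",
            "cup_mask_path": f"cup_{i:03d}.png",
        }
        save_image(out / names["image_path"], img)
        write_boundary_file(out / names["disc_ann_path"], disc_ann)
        write_boundary_file(out / names["cup_ann_path"], cup_ann)
        save_mask(out / names["disc_mask_path"], vol.disc)
        save_mask(out / names["cup_mask_path"], vol.cup)
        rows.append(names)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def phantom_pairs(spec: PhantomSpec, side: int, start: int = 0):
    """Network-ready (image, LabelVolume) pairs, run through the real
    preprocessing path (pad, rescale, rasterize annotations)."""
    from .training import preprocess_pair

    out = []
    for i in range(start, start + spec.n_images):
        img, _, disc_ann, cup_ann = generate_phantom(spec, i)
        x, vol, _ = preprocess_pair(img, disc_ann, cup_ann, side)
        out.append((x, vol))
    return out
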