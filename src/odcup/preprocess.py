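"""Image and annotation preprocessing.

Raw fundus photographs come at arbitrary, usually non-square resolutions,
with structure boundaries supplied as plain-text vertex lists. The network
wants a fixed square input, so the forward path is: center-pad to a square
on the longer side, then rescale to the target side (bilinear for images,
nearest-neighbour for masks). A :class:`PreprocessRecord` captures the pad
offsets and sides so predictions can be mapped back to the original frame.

Coordinate convention: ``(x, y) = (column, row)``, 0-based, pixel centers at
integer coordinates. A rasterized polygon covers every pixel whose center is
inside or exactly on the polygon boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

STRUCTURES = ("disc", "cup")


def _validate_image(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("pixel values must lie in [0, 1]")
    return pixels


@dataclass(frozen=True)
class PreprocessRecord:
    """Geometry bookkeeping for the pad-and-rescale forward transform."""

    original_h: int
    original_w: int
    pad_top: int
    pad_left: int
    square_side: int
    target_side: int

    def __post_init__(self):
        if self.square_side != max(self.original_h, self.original_w):
            raise ValueError("square_side must equal max(original_h, original_w)")
        if self.pad_top < 0 or self.pad_left < 0:
            raise ValueError("pad offsets must be non-negative")
        if self.pad_top + self.original_h > self.square_side or \
                self.pad_left + self.original_w > self.square_side:
            raise ValueError("pad offsets exceed the square side")
        if self.target_side < 1:
            raise ValueError("target_side must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PreprocessRecord":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class BoundaryAnnotation:
    """Polygonal boundary of one structure, as (x, y) vertices."""

    structure: str
    vertices: np.ndarray

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be a (K>=3, 2) array of (x, y)")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if abs(_shoelace(v)) <= 0.0:
            raise ValueError("polygon is degenerate (zero area)")
        object.__setattr__(self, "vertices", v)


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class LabelVolume:
    """Three binary planes: background, optic disc, optic cup.

    Invariants: the cup is nested inside the disc, and the background plane
    is the complement of the disc plane.
    """

    def __init__(self, planes: np.ndarray):
        planes = np.asarray(planes)
        if planes.ndim != 3 or planes.shape[0] != 3:
            raise ValueError(f"expected planes of shape (3, H, W), got {planes.shape}")
        if not np.isin(planes, (0, 1)).all():
            raise ValueError("planes must be binary")
        planes = planes.astype(np.uint8)
        bg, disc, cup = planes
        if np.any(cup > disc):
            raise ValueError("cup plane must be nested inside the disc plane")
        if np.any(bg != 1 - disc):
            raise ValueError("background plane must be the complement of the disc plane")
        self.planes = planes

    @property
    def background(self) -> np.ndarray:
        return self.planes[0]

    @property
    def disc(self) -> np.ndarray:
        return self.planes[1]

    @property
    def cup(self) -> np.ndarray:
        return self.planes[2]

    @property
    def shape(self):
        return self.planes.shape[1:]

    def __eq__(self, other):
        return isinstance(other, LabelVolume) and np.array_equal(self.planes, other.planes)


def pad_to_square(pixels: np.ndarray, fill: float = 0.0):
    """Center-pad an H x W x 3 image to side max(H, W).

    Returns the padded image and a :class:`PreprocessRecord` (with
    ``target_side`` provisionally equal to the square side).
    """
    pixels = _validate_image(pixels)
    h, w = pixels.shape[:2]
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_left = (side - w) // 2
    out = np.full((side, side, 3), float(fill), dtype=pixels.dtype)
    out[pad_top:pad_top + h, pad_left:pad_left + w] = pixels
    rec = PreprocessRecord(original_h=h, original_w=w, pad_top=pad_top,
                           pad_left=pad_left, square_side=side, target_side=side)
    return out, rec


def crop_by_record(pixels: np.ndarray, rec: PreprocessRecord) -> np.ndarray:
    """Exact inverse of :func:`pad_to_square` at the square side."""
    if pixels.shape[0] != rec.square_side or pixels.shape[1] != rec.square_side:
        raise ValueError("image side does not match the record's square_side")
    return pixels[rec.pad_top:rec.pad_top + rec.original_h,
                  rec.pad_left:rec.pad_left + rec.original_w]


def resize_to_side(pixels: np.ndarray, side: int, mode: str = "bilinear") -> np.ndarray:
    """Resize a square image (H x W x C or H x W) to side x side.

    ``bilinear`` for intensity images, ``nearest`` for label masks (preserves
    binarity). No anti-aliasing filter, so the operation is deterministic.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("resize_to_side expects a square input; pad first")
    if mode not in ("bilinear", "nearest"):
        raise ValueError("mode must be 'bilinear' or 'nearest'")
    if pixels.shape[0] == side:
        return pixels.copy()
    order = 1 if mode == "bilinear" else 0
    out_shape = (side, side) + pixels.shape[2:]
    return _sk_resize(pixels, out_shape, order=order, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, side: int) -> np.ndarray:
    """Resample a binary mask to side x side, staying binary.

    The mask is resampled as a float coverage field (area-average) and
    re-thresholded at 0.5. This localizes the boundary to ~half a pixel at
    the coarser of the two resolutions — tighter than nearest-neighbour
    sampling, whose jitter can cost several percent IoU on small structures.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if mask.shape[0] == mask.shape[1] == side:
        return mask.astype(np.uint8)
    resized = resize_to_side(mask.astype(float), side, mode="bilinear")
    return (resized >= 0.5).astype(np.uint8)


def preprocess_image(pixels: np.ndarray, side: int, fill: float = 0.0):
    """Pad to square, then rescale to ``side``; returns (image, record)."""
    padded, rec = pad_to_square(pixels, fill=fill)
    resized = resize_to_side(padded, side, mode="bilinear")
    return resized, replace(rec, target_side=side)


def boundary_to_mask(ann: BoundaryAnnotation, h: int, w: int) -> np.ndarray:
    """Rasterize a boundary polygon onto an h x w binary mask.

    A pixel is set when its center (integer ``(x, y)``) lies inside or on
    the polygon boundary.
    """
    v = ann.vertices
    if np.any(v[:, 0] < -0.5) or np.any(v[:, 0] > w - 0.5) or \
            np.any(v[:, 1] < -0.5) or np.any(v[:, 1] > h - 0.5):
        raise ValueError("vertices fall outside the image bounds")
    poly = Polygon(v)
    if poly.area <= 0.0:
        raise ValueError("polygon is degenerate (zero area)")
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    return inside.reshape(h, w).astype(np.uint8)


def build_label_volume(disc_mask: np.ndarray, cup_mask: np.ndarray) -> LabelVolume:
    """Assemble a nested 3-plane label volume from disc and cup masks.

    Cup pixels outside the disc are absorbed into the disc (the disc grows;
    the cup is never shrunk) and a warning is logged.
    """
    disc = np.asarray(disc_mask)
    cup = np.asarray(cup_mask)
    if disc.shape != cup.shape:
        raise ValueError(f"mask shape mismatch: disc {disc.shape}, cup {cup.shape}")
    if not np.isin(disc, (0, 1)).all() or not np.isin(cup, (0, 1)).all():
        raise ValueError("masks must be binary")
    disc = disc.astype(np.uint8)
    cup = cup.astype(np.uint8)
    outside = int(np.sum((cup == 1) & (disc == 0)))
    if outside:
        logger.warning("absorbing %d cup pixels outside the disc into the disc plane",
                       outside)
    disc_full = np.maximum(disc, cup)
    return LabelVolume(np.stack([1 - disc_full, disc_full, cup]))


def map_prediction_to_original(vol: LabelVolume, rec: PreprocessRecord) -> LabelVolume:
    """Invert the pad-and-rescale transform on a predicted label volume.

    Area-average upscale (see :func:`resize_mask`) from ``target_side`` to
    ``square_side``, then crop the padding away, yielding planes at the
    original resolution.
    """
    if vol.shape != (rec.target_side, rec.target_side):
        raise ValueError(
            f"volume side {vol.shape} does not match record target_side {rec.target_side}"
        )
    planes = []
    for plane in vol.planes:
        up = resize_mask(plane, rec.square_side)
        planes.append(crop_by_record(up[..., None], rec)[..., 0].astype(np.uint8))
    return build_label_volume(planes[1], planes[2])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read an RGB PNG into a float image in [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def save_image(path, pixels: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(pixels, 0, 1) * 255).round().astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG mask as a binary array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127).astype(np.uint8)


def save_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def parse_boundary_file(path, structure: str, delimiter: str | None = None,
                        skip_header: int = 0) -> BoundaryAnnotation:
    """Parse a plain-text boundary file: one ``x y`` (or ``x,y``) pair per line.

    Blank lines and lines starting with ``#`` are ignored. ``delimiter=None``
    accepts either whitespace or commas; the annotation dialect of public
    datasets varies, so header lines can be skipped explicitly.
    """
    verts = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i < skip_header:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                parts = line.replace(",", " ").split()
            else:
                parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}: cannot parse line {i + 1}: {line!r}")
            verts.append((float(parts[0]), float(parts[1])))
    return BoundaryAnnotation(structure=structure, vertices=np.asarray(verts))


def write_boundary_file(path, ann: BoundaryAnnotation) -> None:
    with open(path, "w") as fh:
        for x, y in ann.vertices:
            fh.write(f"{x:.3f} {y:.3f}\n")


def save_record(path, rec: PreprocessRecord) -> None:
    Path(path).write_text(rec.to_json())


def load_record(path) -> PreprocessRecord:
    return PreprocessRecord.from_json(Path(path).read_text())
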