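"""Training loop (multilabel BCE + Adam) and thresholded inference.

Segmentation is framed as a multilabel problem: the three sigmoid output
planes (background, disc, cup) are penalised independently with binary
cross-entropy averaged over every element, so a cup pixel contributes as a
positive to both the disc and the cup plane. The published operating point
is batch size 3 for 900 epochs with Adam; those are the defaults here,
while tests and desk-scale runs pass smaller values explicitly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelConfig, ResCbamUNet, as_batch
from .nn import Adam, no_grad
from .nn import autograd as ag
from .nn.autograd import Tensor
from .preprocess import (LabelVolume, boundary_to_mask, build_label_volume,
                         load_image, map_prediction_to_original,
                         parse_boundary_file, preprocess_image, resize_mask)

logger = logging.getLogger(__name__)

BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 900
    batch_size: int = 3
    learning_rate: float = 1e-3
    threshold: float = 0.5
    seed: int = 0
    device: str = "cpu"
    include_background: bool = True
    stop_below: float | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError("device must be 'cpu' or 'accelerator'")


@dataclass
class TrainingLog:
    epoch_losses: list[float] = field(default_factory=list)
    steps: int = 0
    wall_seconds: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.epoch_losses) + 1),
                             "mean_loss": self.epoch_losses})


def _target_array(t) -> np.ndarray:
    if isinstance(t, LabelVolume):
        return t.planes.astype(np.float32)
    return np.asarray(t, dtype=np.float32)


def bce_loss(p, t):
    """Mean binary cross-entropy between probabilities ``p`` and targets ``t``.

    ``p`` may be a plain array (returns a float) or an autograd tensor
    (returns a scalar tensor on the tape). Probabilities are clipped to
    ``[1e-7, 1 - 1e-7]`` before the logarithms.
    """
    tv = _target_array(t)
    if isinstance(p, Tensor):
        return ag.bce_loss_op(p, tv, eps=BCE_EPS)
    return float(ag.bce_loss_op(Tensor(np.asarray(p, dtype=np.float64)), tv,
                                eps=BCE_EPS).data)


def _as_chw(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a 3-d image array")
    if arr.shape[2] == 3 and arr.shape[0] != 3:
        arr = arr.transpose(2, 0, 1)
    return arr


def train(model_cfg: ModelConfig, train_cfg: TrainingConfig, dataset):
    """Fit the network on ``dataset``: a sequence of (image, LabelVolume).

    Images must already be at ``model_cfg.input_side``. Returns the trained
    model and a per-epoch loss log; fully reproducible for a fixed seed.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if train_cfg.device == "accelerator":
        raise ValueError("no accelerator backend is available; use device='cpu'")
    images = np.stack([_as_chw(img) for img, _ in dataset])
    targets = np.stack([_target_array(t) for _, t in dataset])
    if images.shape[2] != model_cfg.input_side:
        raise ValueError(
            f"dataset images are side {images.shape[2]}, model expects "
            f"{model_cfg.input_side}"
        )
    if not train_cfg.include_background:
        targets = targets[:, 1:]

    model = ResCbamUNet(model_cfg)
    model.train()
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    log = TrainingLog()
    t0 = time.perf_counter()
    n = images.shape[0]
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            x = Tensor(images[idx])
            pred = model(x)
            if not train_cfg.include_background:
                pred = _drop_background(pred)
            loss = ag.bce_loss_op(pred, targets[idx], eps=BCE_EPS)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss ({value}) at epoch {epoch + 1}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
            log.steps += 1
        mean_loss = float(np.mean(losses))
        log.epoch_losses.append(mean_loss)
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, train_cfg.epochs, mean_loss)
        if train_cfg.stop_below is not None and mean_loss < train_cfg.stop_below:
            break
    log.wall_seconds = time.perf_counter() - t0
    return model, log


def _drop_background(pred: Tensor) -> Tensor:
    out_data = pred.data[:, 1:]

    def backward(g):
        full = np.zeros_like(pred.data)
        full[:, 1:] = g
        pred._accumulate(full)

    return ag._make(out_data, (pred,), backward)


def predict(model: ResCbamUNet, pixels: np.ndarray, threshold: float = 0.5,
            restore_original: bool = False) -> LabelVolume:
    """Segment one raw RGB image (any resolution, values in [0, 1]).

    The image is padded/rescaled to the network side, the sigmoid output is
    thresholded per channel, and the disc/cup planes are coerced through
    the nesting rules. With ``restore_original`` the volume is mapped back
    to the input resolution.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    img, rec = preprocess_image(pixels, model.cfg.input_side)
    model.eval()
    with no_grad():
        probs = model(as_batch(img)).data[0]
    disc = (probs[1] >= threshold).astype(np.uint8)
    cup = (probs[2] >= threshold).astype(np.uint8)
    vol = build_label_volume(disc, cup)
    if restore_original:
        vol = map_prediction_to_original(vol, rec)
    return vol


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("image_path", "disc_ann_path", "cup_ann_path")


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df


def preprocess_pair(pixels: np.ndarray, disc_ann, cup_ann, side: int):
    """Produce a network-ready (image, LabelVolume, record) triple.

    Boundary annotations are rasterized at the original resolution, padded
    with the image offsets and resampled with the binary-preserving
    area-average scheme of :func:`odcup.preprocess.resize_mask`.
    """
    h, w = pixels.shape[:2]
    disc = boundary_to_mask(disc_ann, h, w)
    cup = boundary_to_mask(cup_ann, h, w)
    img, rec = preprocess_image(pixels, side)
    planes = []
    for mask in (disc, cup):
        padded = np.zeros((rec.square_side, rec.square_side), dtype=np.uint8)
        padded[rec.pad_top:rec.pad_top + h, rec.pad_left:rec.pad_left + w] = mask
        planes.append(resize_mask(padded, side))
    return img, build_label_volume(planes[0], planes[1]), rec


def load_dataset(manifest_path, side: int, root=None):
    """Load every manifest row into (image, LabelVolume) pairs at ``side``."""
    df = load_manifest(manifest_path)
    base = Path(root) if root is not None else Path(manifest_path).parent
    out = []
    for row in df.itertuples(index=False):
        pixels = load_image(_resolve(base, row.image_path))
        disc_ann = parse_boundary_file(_resolve(base, row.disc_ann_path), "disc")
        cup_ann = parse_boundary_file(_resolve(base, row.cup_ann_path), "cup")
        img, vol, _ = preprocess_pair(pixels, disc_ann, cup_ann, side)
        out.append((img, vol))
    return out


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p
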