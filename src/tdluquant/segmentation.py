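"""U-Net tissue segmentation: patch sampling, augmentation, training, tiled inference.

The network predicts the 7-class label map (plus ignored background) from
RGB tiles. Training follows the augmentation suite of the annotation
protocol — flips, right-angle rotations, Gaussian noise, Gaussian blur and
color jitter — with background (code 0) masked from the pixelwise
cross-entropy, since real slides are annotated only inside selected TDLU
rectangles. Inference tiles large images and averages class scores in
overlapping regions before the argmax.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import classes as C
from .annotations import LabelMap, read_label_map
from .nn import Adam, UNet, masked_softmax_cross_entropy, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "SegConfig",
    "TrainedSegmenter",
    "sample_patches",
    "augment",
    "train",
    "predict",
    "save_segmenter",
    "load_segmenter",
]

DEFAULT_AUGMENTATIONS = ("flip", "rotate90", "gaussian_noise", "gaussian_blur", "color_jitter")


@dataclass
class SegConfig:
    """Hyperparameters of the segmentation network and its training run."""

    patch_size: int = 512
    n_classes: int = 8  # codes 0-7; background masked from the loss
    depth: int = 4
    base_filters: int = 32
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 1e-3
    n_patches_per_scene: int = 8
    augmentations: tuple[str, ...] = DEFAULT_AUGMENTATIONS
    noise_sd: float = 0.03  # on [0,1]-scaled intensities
    blur_sigma_max: float = 1.2
    color_jitter: float = 0.06
    class_weighting: str = "balanced"  # "balanced" (1/sqrt freq) or "none"
    lr_decay: float = 0.1  # final-epoch learning rate as a fraction of initial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2**self.depth != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^depth={2**self.depth}"
            )
        unknown = set(self.augmentations) - set(DEFAULT_AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")


@dataclass
class TrainedSegmenter:
    network: UNet
    config: SegConfig
    history: pd.DataFrame | None = None
    class_names: dict[int, str] = field(default_factory=lambda: dict(C.CLASS_NAMES))


def _normalize(rgb: np.ndarray) -> np.ndarray:
    return (rgb.astype(np.float32) / 255.0) - 0.5


def _load_scene(row) -> tuple[np.ndarray, np.ndarray]:
    from PIL import Image

    rgb = np.asarray(Image.open(row["image_path"]).convert("RGB"))
    labels = read_label_map(row["label_path"]).codes
    if rgb.shape[:2] != labels.shape:
        raise ValueError(f"image/label extent mismatch for {row['image_path']}")
    return rgb, labels


def sample_patches(
    manifest: pd.DataFrame,
    patch_size: int,
    n_per_scene: int,
    seed: int,
    scenes: list[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Yield (rgb patch, label patch) pairs drawn from manifest scenes.

    Each patch contains at least one annotated (non-background) pixel;
    half the draws are centered on rare-class pixels (epithelium, lumen,
    border, vessel) so lobular structure is not swamped by stroma.
    All-background scenes yield nothing, with a warning. Scenes smaller
    than the patch are zero-padded with background. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if scenes is None:
        scenes = [_load_scene(row) for _, row in manifest.iterrows()]
    for rgb, labels in scenes:
        if not (labels != C.BACKGROUND).any():
            logger.warning("scene without annotated pixels; skipped")
            continue
        h, w = labels.shape
        if h < patch_size or w < patch_size:
            pad_h, pad_w = max(0, patch_size - h), max(0, patch_size - w)
            logger.warning("scene smaller than patch; zero-padding with background")
            rgb = np.pad(rgb, ((0, pad_h), (0, pad_w), (0, 0)))
            labels = np.pad(labels, ((0, pad_h), (0, pad_w)))
            h, w = labels.shape
        rare = np.argwhere(
            np.isin(labels, (C.EPITHELIUM, C.LUMEN, C.BORDER, C.VESSEL))
        )
        annotated = np.argwhere(labels != C.BACKGROUND)
        for _ in range(n_per_scene):
            for _attempt in range(50):
                if len(rare) and rng.uniform() < 0.5:
                    cy, cx = rare[rng.integers(len(rare))]
                    y0 = int(np.clip(cy - patch_size // 2, 0, h - patch_size))
                    x0 = int(np.clip(cx - patch_size // 2, 0, w - patch_size))
                else:
                    y0 = int(rng.integers(0, h - patch_size + 1))
                    x0 = int(rng.integers(0, w - patch_size + 1))
                lab = labels[y0 : y0 + patch_size, x0 : x0 + patch_size]
                if (lab != C.BACKGROUND).any():
                    break
            else:  # fall back to a patch around any annotated pixel
                cy, cx = annotated[rng.integers(len(annotated))]
                y0 = int(np.clip(cy - patch_size // 2, 0, h - patch_size))
                x0 = int(np.clip(cx - patch_size // 2, 0, w - patch_size))
                lab = labels[y0 : y0 + patch_size, x0 : x0 + patch_size]
            yield rgb[y0 : y0 + patch_size, x0 : x0 + patch_size], lab


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    augmentations=DEFAULT_AUGMENTATIONS,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.03,
    blur_sigma_max: float = 1.2,
    color_jitter: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the training augmentation suite to one (image, label) pair.

    Geometric transforms (flips, 90-degree rotations) act identically on
    image and labels; intensity transforms (noise, blur, per-channel color
    scale/shift) act on the image only. ``image`` is float on the [-0.5,
    0.5] normalized scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if "flip" in augmentations:
        if rng.uniform() < 0.5:
            image, labels = image[::-1], labels[::-1]
        if rng.uniform() < 0.5:
            image, labels = image[:, ::-1], labels[:, ::-1]
    if "rotate90" in augmentations:
        k = int(rng.integers(0, 4))
        image, labels = np.rot90(image, k), np.rot90(labels, k)
    image = np.ascontiguousarray(image, dtype=np.float32)
    labels = np.ascontiguousarray(labels)
    if "color_jitter" in augmentations:
        scale = rng.uniform(1 - color_jitter, 1 + color_jitter, size=3).astype(np.float32)
        shift = rng.uniform(-color_jitter / 2, color_jitter / 2, size=3).astype(np.float32)
        image = image * scale + shift
    if "gaussian_blur" in augmentations and rng.uniform() < 0.5:
        sigma = rng.uniform(0.3, blur_sigma_max)
        image = ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0))
    if "gaussian_noise" in augmentations and rng.uniform() < 0.5:
        image = image + rng.normal(0.0, noise_sd, size=image.shape).astype(np.float32)
    return image.astype(np.float32), labels


def _batches(patches, batch_size):
    imgs, labs = [], []
    for img, lab in patches:
        imgs.append(img.transpose(2, 0, 1))
        labs.append(lab)
        if len(imgs) == batch_size:
            yield np.stack(imgs), np.stack(labs).astype(np.int64)
            imgs, labs = [], []
    if imgs:
        yield np.stack(imgs), np.stack(labs).astype(np.int64)


def train(
    config: SegConfig,
    manifest: pd.DataFrame,
    scenes: dict[str, list[tuple[np.ndarray, np.ndarray]]] | None = None,
    log_path: str | Path | None = None,
) -> TrainedSegmenter:
    """Train the U-Net on the manifest's train split, validating per epoch.

    Loss is pixelwise cross-entropy with background excluded. The weights
    with the best validation loss are returned; the per-epoch training
    curve is kept on the result (and written to CSV when ``log_path`` is
    given). ``scenes`` may supply preloaded {"train": [...], "val": [...]}
    (rgb, label) arrays to skip disk I/O.
    """
    if scenes is None:
        scenes = {}
        for split in ("train", "val"):
            rows = manifest[manifest["split"] == split]
            if rows.empty:
                raise ValueError(f"manifest has no '{split}' split")
            scenes[split] = [_load_scene(row) for _, row in rows.iterrows()]
    for split in ("train", "val"):
        if not scenes.get(split):
            raise ValueError(f"empty '{split}' split")

    class_weights = None
    if config.class_weighting == "balanced":
        # inverse-sqrt frequency over the training labels; rare classes
        # (lumen, vessel, border) otherwise destabilize under plain CE
        hist = np.zeros(config.n_classes, dtype=np.float64)
        for _, labels in scenes["train"]:
            hist += np.bincount(labels.ravel(), minlength=config.n_classes)
        freq = hist / max(hist[1:].sum(), 1.0)
        with np.errstate(divide="ignore"):
            class_weights = np.where(freq > 0, 1.0 / np.sqrt(freq), 0.0)
        class_weights[C.BACKGROUND] = 0.0
        present = class_weights > 0
        class_weights[present] /= class_weights[present].mean()
    elif config.class_weighting != "none":
        raise ValueError("class_weighting must be 'balanced' or 'none'")

    rng = np.random.default_rng(config.seed)
    net = UNet(
        in_channels=3,
        n_classes=config.n_classes,
        depth=config.depth,
        base_filters=config.base_filters,
        seed=config.seed,
    )
    optimizer = Adam(net.parameters(), lr=config.learning_rate)

    val_patches = [
        (_normalize(img), lab)
        for img, lab in sample_patches(
            manifest,
            config.patch_size,
            max(2, config.n_patches_per_scene // 2),
            seed=config.seed + 101,
            scenes=scenes["val"],
        )
    ]

    best_loss, best_weights = np.inf, net.get_weights()
    history = []
    for epoch in range(config.epochs):
        if config.epochs > 1:
            optimizer.lr = config.learning_rate * config.lr_decay ** (
                epoch / (config.epochs - 1)
            )
        epoch_seed = int(rng.integers(0, 2**31 - 1))
        aug_rng = np.random.default_rng(epoch_seed)
        train_losses = []
        patches = (
            augment(
                _normalize(img),
                lab,
                config.augmentations,
                aug_rng,
                config.noise_sd,
                config.blur_sigma_max,
                config.color_jitter,
            )
            for img, lab in sample_patches(
                manifest,
                config.patch_size,
                config.n_patches_per_scene,
                seed=epoch_seed,
                scenes=scenes["train"],
            )
        )
        for images, labels in _batches(patches, config.batch_size):
            logits = net.forward(images, train=True)
            loss, grad = masked_softmax_cross_entropy(
                logits, labels, class_weights=class_weights
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate"
                )
            net.zero_grad()
            net.backward(grad)
            optimizer.step()
            train_losses.append(loss)

        val_losses = []
        for images, labels in _batches(iter(val_patches), config.batch_size):
            logits = net.forward(images, train=False)
            loss, _ = masked_softmax_cross_entropy(
                logits, labels, class_weights=class_weights
            )
            val_losses.append(loss)
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses))
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
        if val_loss < best_loss:
            best_loss, best_weights = val_loss, net.get_weights()

    net.set_weights(best_weights)
    hist = pd.DataFrame(history)
    if log_path is not None:
        hist.to_csv(log_path, index=False)
    return TrainedSegmenter(network=net, config=config, history=hist)


def predict(
    segmenter: TrainedSegmenter,
    image: np.ndarray,
    tile_size: int = 256,
    overlap: int = 32,
    resolution: float = 0.495,
) -> LabelMap:
    """Tiled whole-image inference; argmax of averaged class scores.

    Tiles of ``tile_size`` advance by ``tile_size - overlap``; softmax
    scores are averaged where tiles overlap before the per-pixel argmax,
    with a linear taper over the overlap margin so pixels near a tile edge
    (whose receptive field is clipped) defer to the neighboring tile's
    interior prediction. Output extent equals input.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB (H, W, 3) image")
    if overlap >= tile_size:
        raise ValueError("overlap must be smaller than tile_size")
    h, w = image.shape[:2]
    div = 2**segmenter.config.depth
    tile = min(tile_size, max(h, w))
    tile = max(div, (tile + div - 1) // div * div)
    norm = _normalize(image)
    scores = np.zeros((segmenter.config.n_classes, h, w), dtype=np.float32)
    weight = np.zeros((h, w), dtype=np.float32)
    stride = tile - overlap
    ramp = np.minimum(np.arange(1, tile + 1), np.arange(tile, 0, -1)).astype(
        np.float32
    )
    ramp = np.minimum(ramp / (overlap + 1), 1.0) if overlap > 0 else np.ones(tile, np.float32)
    taper = ramp[:, None] * ramp[None, :]
    ys = sorted({min(y, max(0, h - tile)) for y in range(0, max(h - tile, 0) + stride, stride)})
    xs = sorted({min(x, max(0, w - tile)) for x in range(0, max(w - tile, 0) + stride, stride)})
    for y0 in ys:
        for x0 in xs:
            patch = norm[y0 : y0 + tile, x0 : x0 + tile]
            ph, pw = patch.shape[:2]
            if ph < tile or pw < tile:
                patch = np.pad(patch, ((0, tile - ph), (0, tile - pw), (0, 0)))
            logits = segmenter.network.forward(
                patch.transpose(2, 0, 1)[None], train=False
            )[0]
            probs = softmax(logits, axis=0)[:, :ph, :pw]
            tw = taper[:ph, :pw]
            scores[:, y0 : y0 + ph, x0 : x0 + pw] += probs * tw[None]
            weight[y0 : y0 + ph, x0 : x0 + pw] += tw
    scores /= weight[None]
    codes = scores.argmax(axis=0).astype(np.uint8)
    return LabelMap(codes, resolution)


def save_segmenter(segmenter: TrainedSegmenter, path: str | Path) -> None:
    """Write a checkpoint (npz weights + embedded config JSON)."""
    weights = segmenter.network.get_weights()
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    np.savez_compressed(
        str(path), config=json.dumps(asdict(segmenter.config)), **arrays
    )


def load_segmenter(path: str | Path) -> TrainedSegmenter:
    data = np.load(str(path), allow_pickle=False)
    cfg_dict = json.loads(str(data["config"]))
    cfg_dict["augmentations"] = tuple(cfg_dict["augmentations"])
    config = SegConfig(**cfg_dict)
    net = UNet(
        in_channels=3,
        n_classes=config.n_classes,
        depth=config.depth,
        base_filters=config.base_filters,
        seed=config.seed,
    )
    weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    net.set_weights(weights)
    return TrainedSegmenter(network=net, config=config)
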