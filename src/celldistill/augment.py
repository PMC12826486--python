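"""Multi-crop view generation and microscopy-specific augmentations.

The self-distillation objective compares network outputs across random views
of the same image: a small number of large "global" crops (seen by teacher
and student) and optionally many small "local" crops (student only).  The
transform suite is the one appropriate for multi-channel fluorescence data:
random resized crops, flips, per-channel brightness/contrast jitter, random
rescaling of the protein channel, and dropping one randomly chosen channel
by zeroing all of its pixels.  Gaussian blur, solarization and greyscale
conversion — standard for natural RGB images — are deliberately absent.

Every view ends with per-channel self-normalization (mean subtraction,
division by the standard deviation), which also makes views invariant to
per-channel affine intensity changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError
from .image import MultiChannelImage

SELF_NORMALIZE_EPS = 1e-6


@dataclass
class CropConfig:
    n_global: int = 2
    global_size: int = 32
    n_local: int = 4
    local_size: int = 16
    global_scale_range: tuple[float, float] = (0.32, 1.0)
    local_scale_range: tuple[float, float] = (0.05, 0.32)

    def validate(self) -> None:
        if self.n_global < 2:
            raise ConfigurationError("self-distillation needs >= 2 global views")
        if self.n_local < 0:
            raise ConfigurationError("n_local must be >= 0")
        if self.n_local > 0 and self.local_size > self.global_size:
            raise ConfigurationError("local_size must not exceed global_size")
        for lo, hi in (self.global_scale_range, self.local_scale_range):
            if not (0 < lo <= hi <= 1):
                raise ConfigurationError("scale ranges must satisfy 0 < lo <= hi <= 1")


@dataclass
class AugConfig:
    p_channel_drop: float = 0.2
    brightness_delta: float = 0.2
    contrast_range: tuple[float, float] = (0.8, 1.2)
    protein_gain_range: tuple[float, float] = (0.5, 1.5)
    protein_channel_index: int | None = None
    flips: bool = True

    def validate(self) -> None:
        if not 0 <= self.p_channel_drop <= 1:
            raise ConfigurationError("p_channel_drop must be a probability")
        if self.contrast_range[0] > self.contrast_range[1]:
            raise ConfigurationError("contrast_range must be ordered")
        if self.protein_gain_range[0] > self.protein_gain_range[1]:
            raise ConfigurationError("protein_gain_range must be ordered")


@dataclass
class ViewSet:
    global_views: list[MultiChannelImage]
    local_views: list[MultiChannelImage]
    provenance: list[dict] = field(default_factory=list)

    @property
    def all_views(self) -> list[MultiChannelImage]:
        return self.global_views + self.local_views


def hpa_preset(global_size: int = 32, local_size: int = 16) -> tuple[CropConfig, AugConfig]:
    """4-channel protein-localization preset: local crops on, protein rescale on."""
    crop = CropConfig(n_global=2, global_size=global_size, n_local=4, local_size=local_size)
    aug = AugConfig(protein_channel_index=3)
    return crop, aug


def cellpainting_preset(global_size: int = 128) -> tuple[CropConfig, AugConfig]:
    """5-channel profiling preset: no local crops, no protein-specific rescale."""
    crop = CropConfig(n_global=2, global_size=global_size, n_local=0, local_size=global_size)
    aug = AugConfig(protein_channel_index=None)
    return crop, aug


# ---------------------------------------------------------------------------
# individual transforms
# ---------------------------------------------------------------------------

def self_normalize(img: MultiChannelImage) -> MultiChannelImage:
    """Per-channel (x - mean) / (std + eps); constant channels map to zeros."""
    x = img.data
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    return MultiChannelImage((x - mu) / (sd + SELF_NORMALIZE_EPS), img.channels)


def random_channel_drop(img: MultiChannelImage, p: float,
                        rng: np.random.Generator) -> MultiChannelImage:
    """With probability p, zero out all pixels of one uniformly chosen channel."""
    if img.n_channels < 2:
        raise ConfigurationError("channel drop needs >= 2 channels")
    if rng.uniform() < p:
        c = int(rng.integers(0, img.n_channels))
        out = img.data.copy()
        out[c] = 0.0
        return MultiChannelImage(out, img.channels)
    return img.copy()


def channel_jitter(img: MultiChannelImage, cfg: AugConfig,
                   rng: np.random.Generator) -> tuple[MultiChannelImage, dict]:
    """Independent per-channel brightness shift and contrast gain about the mean."""
    cfg.validate()
    C = img.n_channels
    gains = rng.uniform(cfg.contrast_range[0], cfg.contrast_range[1], size=C)
    shifts = rng.uniform(-cfg.brightness_delta, cfg.brightness_delta, size=C)
    mu = img.data.mean(axis=(1, 2), keepdims=True)
    out = gains[:, None, None] * (img.data - mu) + mu + shifts[:, None, None]
    np.clip(out, 0.0, 1.0, out=out)
    return (MultiChannelImage(out, img.channels),
            {"gains": gains.tolist(), "shifts": shifts.tolist()})


def protein_rescale(img: MultiChannelImage, idx: int,
                    gain_range: tuple[float, float],
                    rng: np.random.Generator) -> tuple[MultiChannelImage, float]:
    """Multiply only the protein channel by a random gain, clipped to [0, 1]."""
    if not 0 <= idx < img.n_channels:
        raise ConfigurationError(f"protein channel index {idx} out of range")
    gain = float(rng.uniform(gain_range[0], gain_range[1]))
    out = img.data.copy()
    out[idx] = np.clip(out[idx] * gain, 0.0, 1.0)
    return MultiChannelImage(out, img.channels), gain


def _random_resized_crop(img: MultiChannelImage, size: int,
                         scale_range: tuple[float, float],
                         rng: np.random.Generator) -> tuple[MultiChannelImage, dict]:
    """Sample an area fraction and aspect ratio, crop, and resize to ``size``."""
    C, H, W = img.data.shape
    for _ in range(10):
        area = rng.uniform(scale_range[0], scale_range[1]) * H * W
        log_ratio = rng.uniform(np.log(3 / 4), np.log(4 / 3))
        ratio = np.exp(log_ratio)
        h = int(round(np.sqrt(area / ratio)))
        w = int(round(np.sqrt(area * ratio)))
        if 0 < h <= H and 0 < w <= W:
            break
    else:
        h = w = min(H, W)
    y0 = int(rng.integers(0, H - h + 1))
    x0 = int(rng.integers(0, W - w + 1))
    crop = img.data[:, y0:y0 + h, x0:x0 + w]
    if (h, w) != (size, size):
        crop = resize(crop, (C, size, size), order=1, mode="reflect",
                      anti_aliasing=False, preserve_range=True)
    return (MultiChannelImage(crop, img.channels),
            {"y0": y0, "x0": x0, "h": h, "w": w,
             "area_fraction": h * w / (H * W)})


def _augment_one_view(img: MultiChannelImage, size: int, scale_range,
                      aug_cfg: AugConfig, rng: np.random.Generator
                      ) -> tuple[MultiChannelImage, dict]:
    view, prov = _random_resized_crop(img, size, scale_range, rng)
    if aug_cfg.flips:
        flip_h = bool(rng.integers(0, 2))
        flip_v = bool(rng.integers(0, 2))
        data = view.data
        if flip_h:
            data = data[:, :, ::-1]
        if flip_v:
            data = data[:, ::-1, :]
        view = MultiChannelImage(np.ascontiguousarray(data), view.channels)
        prov.update({"flip_h": flip_h, "flip_v": flip_v})
    view, jitter_prov = channel_jitter(view, aug_cfg, rng)
    prov.update(jitter_prov)
    if aug_cfg.protein_channel_index is not None:
        view, gain = protein_rescale(view, aug_cfg.protein_channel_index,
                                     aug_cfg.protein_gain_range, rng)
        prov["protein_gain"] = gain
    view = random_channel_drop(view, aug_cfg.p_channel_drop, rng)
    view = self_normalize(view)
    return view, prov


def multi_crop(img: MultiChannelImage, crop_cfg: CropConfig, aug_cfg: AugConfig,
               rng: np.random.Generator) -> ViewSet:
    """Generate the global/local augmented views of one image.

    Order of operations per view: random-resized-crop -> flips -> per-channel
    jitter -> protein rescale -> channel drop -> self-normalize.
    """
    crop_cfg.validate()
    aug_cfg.validate()
    globals_, locals_, prov = [], [], []
    for _ in range(crop_cfg.n_global):
        v, p = _augment_one_view(img, crop_cfg.global_size,
                                 crop_cfg.global_scale_range, aug_cfg, rng)
        globals_.append(v)
        p["kind"] = "global"
        prov.append(p)
    for _ in range(crop_cfg.n_local):
        v, p = _augment_one_view(img, crop_cfg.local_size,
                                 crop_cfg.local_scale_range, aug_cfg, rng)
        locals_.append(v)
        p["kind"] = "local"
        prov.append(p)
    return ViewSet(globals_, locals_, prov)


def center_crop(img: MultiChannelImage, size: int) -> MultiChannelImage:
    """Center crop to (size, size); smaller images are reflect-padded first."""
    data = img.data
    _, H, W = data.shape
    pad_h = max(size - H, 0)
    pad_w = max(size - W, 0)
    if pad_h or pad_w:
        data = np.pad(data, ((0, 0),
                             (pad_h // 2, pad_h - pad_h // 2),
                             (pad_w // 2, pad_w - pad_w // 2)), mode="reflect")
        _, H, W = data.shape
    y0, x0 = (H - size) // 2, (W - size) // 2
    return MultiChannelImage(data[:, y0:y0 + size, x0:x0 + size].copy(), img.channels)


def eval_transform(img: MultiChannelImage, crop_size: int) -> MultiChannelImage:
    """Deterministic inference transform: center crop then self-normalization."""
    return self_normalize(center_crop(img, crop_size))
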