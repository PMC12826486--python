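"""Channel-configurable vision transformer backbone.

The image is tokenized as a sequence of non-overlapping p x p patches
(row-major, 0-based); each patch is flattened across all C channels and
linearly projected to the model width.  A learned class token is prepended
and learned position encodings are added; the sequence then passes through
pre-norm transformer blocks.  The embedding readout used throughout the
package is the concatenation of the class token with the average-pooled
patch tokens of the last block — length exactly 2 x width.

Inference at a size other than the training size interpolates the 2-D grid
of position encodings bicubically (the operation is exact at the training
size).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ConfigurationError
from .image import MultiChannelImage


@dataclass
class BackboneConfig:
    n_channels: int = 4
    patch_size: int = 8
    width: int = 32
    depth: int = 2
    n_heads: int = 4
    image_size: int = 32

    def validate(self) -> None:
        if self.width % self.n_heads:
            raise ConfigurationError("width must be divisible by n_heads")
        if self.image_size % self.patch_size:
            raise ConfigurationError("image_size must be divisible by patch_size")


@dataclass
class TokenOutput:
    class_token: nn.Tensor          # (B, d)
    patch_tokens: nn.Tensor         # (B, N, d)
    grid: tuple[int, int]           # (rows, cols)
    per_layer: list[nn.Tensor]      # last-L layers' patch tokens, oldest first


def patchify(images: np.ndarray, p: int) -> np.ndarray:
    """(B, C, H, W) -> (B, N, C*p*p) in row-major patch order."""
    b, c, h, w = images.shape
    if h % p or w % p:
        raise ConfigurationError(f"image {h}x{w} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    x = images.reshape(b, c, gh, p, gw, p)
    return x.transpose(0, 2, 4, 1, 3, 5).reshape(b, gh * gw, c * p * p)


class VisionTransformer(nn.Module):
    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        d = cfg.width
        self.grid_train = cfg.image_size // cfg.patch_size
        n_patches = self.grid_train ** 2
        self.register("patch_proj", nn.Linear(cfg.n_channels * cfg.patch_size ** 2, d, rng))
        self.register("cls_token", nn.trunc_normal(rng, (1, 1, d)))
        self.register("pos_embed", nn.trunc_normal(rng, (1, n_patches + 1, d)))
        self.register("mask_token", nn.trunc_normal(rng, (1, 1, d)))
        for i in range(cfg.depth):
            self.register(f"block{i}", nn.TransformerBlock(d, cfg.n_heads, rng))
        self.register("norm", nn.LayerNorm(d))
        self._interp_cache: dict[tuple[int, int], np.ndarray] = {}

    # -- position encodings -------------------------------------------------
    def _interp_matrix(self, gh: int, gw: int) -> np.ndarray:
        """Linear map sending the training pos-embed grid to a (gh, gw) grid."""
        key = (gh, gw)
        if key not in self._interp_cache:
            g = self.grid_train
            basis = np.eye(g * g).reshape(g * g, g, g)
            out = resize(basis, (g * g, gh, gw), order=3, mode="edge",
                         anti_aliasing=False, preserve_range=True)
            self._interp_cache[key] = out.reshape(g * g, gh * gw).T.copy()
        return self._interp_cache[key]

    def _pos_for(self, gh: int, gw: int) -> nn.Tensor:
        cls_pos = self.pos_embed[:, :1, :]
        patch_pos = self.pos_embed[:, 1:, :]
        if (gh, gw) != (self.grid_train, self.grid_train):
            m = nn.Tensor(self._interp_matrix(gh, gw))
            patch_pos = (m @ patch_pos[0]).reshape(1, gh * gw, self.cfg.width)
        return nn.Tensor.cat([cls_pos, patch_pos], axis=1)

    # -- forward -----------------------------------------------------------
    def forward(self, images: np.ndarray, mask: np.ndarray | None = None,
                capture_layers: int = 0) -> TokenOutput:
        """Run the backbone on a (B, C, H, W) batch.

        ``mask`` (B, N) marks patch tokens to replace with the learned mask
        token (masked-image-modelling branch).  ``capture_layers`` keeps the
        patch tokens of that many final blocks.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        b, c, h, w = images.shape
        if c != self.cfg.n_channels:
            raise ConfigurationError(
                f"backbone expects {self.cfg.n_channels} channels, got {c}")
        p = self.cfg.patch_size
        gh, gw = h // p, w // p
        tokens = self.patch_proj(nn.Tensor(patchify(images, p)))  # (B, N, d)
        if mask is not None:
            m = np.asarray(mask, dtype=np.float64)[:, :, None]
            tokens = tokens * (1.0 - m) + self.mask_token * m
        cls = nn.Tensor.cat([self.cls_token] * b, axis=0)  # (B, 1, d)
        x = nn.Tensor.cat([cls, tokens], axis=1) + self._pos_for(gh, gw)

        captured: list[nn.Tensor] = []
        depth = self.cfg.depth
        for i in range(depth):
            x = getattr(self, f"block{i}")(x)
            if capture_layers and i >= depth - capture_layers:
                captured.append(self.norm(x)[:, 1:, :])
        x = self.norm(x)
        return TokenOutput(class_token=x[:, 0, :], patch_tokens=x[:, 1:, :],
                           grid=(gh, gw), per_layer=captured)

    def embed(self, images: np.ndarray) -> nn.Tensor:
        """concat(class token, mean of patch tokens): (B, 2*width)."""
        out = self.forward(images)
        pooled = out.patch_tokens.mean(axis=1)
        return nn.Tensor.cat([out.class_token, pooled], axis=1)

    def embed_image(self, img: MultiChannelImage) -> np.ndarray:
        return self.embed(img.data[None]).data[0]


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: VisionTransformer, extra: dict | None = None,
                    head_state: dict[str, np.ndarray] | None = None) -> None:
    """Write config + weights (+ optional projection-head state) to a zip."""
    with zipfile.ZipFile(path, "w") as zf:
        meta = {"config": asdict(model.cfg), "extra": extra or {}}
        zf.writestr("meta.json", json.dumps(meta))
        for prefix, state in (("backbone", model.state_dict()),
                              ("head", head_state or {})):
            for k, v in state.items():
                buf = io.BytesIO()
                np.save(buf, v)
                zf.writestr(f"{prefix}/{k}.npy", buf.getvalue())


def load_checkpoint(path) -> tuple[VisionTransformer, dict, dict[str, np.ndarray]]:
    """Load a checkpoint; returns (backbone, extra metadata, head state)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        model = VisionTransformer(BackboneConfig(**meta["config"]))
        backbone_state, head_state = {}, {}
        for name in zf.namelist():
            if name == "meta.json":
                continue
            prefix, key = name.split("/", 1)
            arr = np.load(io.BytesIO(zf.read(name)))
            if prefix == "backbone":
                backbone_state[key[:-4]] = arr
            else:
                head_state[key[:-4]] = arr
        model.load_state_dict(backbone_state)
    return model, meta["extra"], head_state
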