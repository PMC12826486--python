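"""Frozen-backbone embedding and patch-token extraction over an image index."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .augment import eval_transform
from .image import MultiChannelImage
from .vit import VisionTransformer, load_checkpoint


@dataclass
class EmbeddingTable:
    """One embedding row per index entry, metadata carried alongside."""

    embeddings: np.ndarray       # (n, 2*width)
    metadata: pd.DataFrame
    failures: list[dict]

    def __post_init__(self):
        if len(self.embeddings) != len(self.metadata):
            raise ValueError("embeddings and metadata row counts differ")

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        self.metadata.to_csv(prefix.with_suffix(".csv"), index=False)
        np.save(prefix.with_suffix(".npy"), self.embeddings)
        if self.failures:
            pd.DataFrame(self.failures).to_csv(
                prefix.parent / (prefix.name + "_failures.csv"), index=False)

    @classmethod
    def load(cls, prefix) -> "EmbeddingTable":
        prefix = Path(prefix)
        return cls(np.load(prefix.with_suffix(".npy")),
                   pd.read_csv(prefix.with_suffix(".csv")), [])


@dataclass
class PatchTokenMap:
    image_id: str
    grids: list[np.ndarray]      # per requested layer: (rows, cols, width)
    patch_size: int
    rows: int
    cols: int


def _read_image(row: pd.Series, path_cols: list[str],
                channels: tuple[str, ...]) -> MultiChannelImage:
    planes = [tifffile.imread(row[c]).astype(np.float64) / 65535.0 for c in path_cols]
    return MultiChannelImage(np.stack(planes), channels)


def _as_model(model_or_ckpt) -> VisionTransformer:
    if isinstance(model_or_ckpt, VisionTransformer):
        return model_or_ckpt
    model, _, _ = load_checkpoint(model_or_ckpt)
    return model


def extract_embeddings(model_or_ckpt, index: pd.DataFrame, crop_size: int,
                       images: list[MultiChannelImage] | None = None,
                       batch_size: int = 32) -> EmbeddingTable:
    """Embed every index row with the frozen backbone.

    Each image goes through the deterministic inference transform (center
    crop + self-normalization) and the backbone's embedding readout.  Rows
    whose raster files cannot be read are reported in the failure manifest
    and excluded; the run continues.
    """
    model = _as_model(model_or_ckpt)
    path_cols = [c for c in index.columns if c.startswith("path_")]
    channels = tuple(c[len("path_"):] for c in path_cols)

    prepared, kept, failures = [], [], []
    for i, (_, row) in enumerate(index.iterrows()):
        try:
            img = images[i] if images is not None else _read_image(row, path_cols, channels)
            prepared.append(eval_transform(img, crop_size).data)
            kept.append(i)
        except Exception as exc:  # noqa: BLE001 - row-level error report
            failures.append({"row": i, "image_id": row.get("image_id", i),
                             "error": str(exc)})

    embs = []
    for lo in range(0, len(prepared), batch_size):
        batch = np.stack(prepared[lo:lo + batch_size])
        embs.append(model.embed(batch).data)
    embeddings = np.concatenate(embs) if embs else np.zeros((0, 2 * model.cfg.width))
    if not np.isfinite(embeddings).all():
        raise RuntimeError("non-finite values in extracted embeddings")
    meta = index.iloc[kept].reset_index(drop=True)
    return EmbeddingTable(embeddings, meta, failures)


def extract_cell_embeddings(model_or_ckpt, image: MultiChannelImage,
                            cell_masks: np.ndarray, crop_size: int) -> np.ndarray:
    """Embed a crop centered on each labelled cell of one scene.

    Each crop is exactly centered on the cell centroid (the image is
    reflect-padded so border cells are not shifted off-center) and goes
    through the standard inference transform.  Returns an
    (n_cells, 2*width) matrix in label order.
    """
    model = _as_model(model_or_ckpt)
    labels = [l for l in np.unique(cell_masks) if l > 0]
    half = crop_size // 2
    padded = np.pad(image.data, ((0, 0), (half, half), (half, half)), mode="reflect")
    crops = []
    for lab in labels:
        ys, xs = np.nonzero(cell_masks == lab)
        cy, cx = int(ys.mean()), int(xs.mean())
        sub = MultiChannelImage(padded[:, cy:cy + crop_size, cx:cx + crop_size],
                                image.channels)
        crops.append(eval_transform(sub, crop_size).data)
    if not crops:
        return np.zeros((0, 2 * model.cfg.width))
    return model.embed(np.stack(crops)).data


def extract_patch_tokens(model_or_ckpt, image: MultiChannelImage,
                         n_layers: int = 1, image_id: str = "",
                         crop_size: int | None = None) -> PatchTokenMap:
    """Per-layer patch-token grids (class token excluded) for one image."""
    model = _as_model(model_or_ckpt)
    if crop_size is not None:
        image = eval_transform(image, crop_size)
    out = model.forward(image.data[None], capture_layers=n_layers)
    rows, cols = out.grid
    grids = [t.data[0].reshape(rows, cols, model.cfg.width) for t in out.per_layer]
    return PatchTokenMap(image_id, grids, model.cfg.patch_size, rows, cols)
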