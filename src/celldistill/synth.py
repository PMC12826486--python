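"""Synthetic multi-channel fluorescence scenes with ground truth.

Every downstream module in this package is exercised on images produced
here, so the generator emulates the structure of the two assay families the
toolkit targets:

* HPA-style 4-channel images (nucleus, microtubules, ER, protein of
  interest) where the protein channel follows a subcellular localization
  class, optionally with per-cell heterogeneity;
* Cell-Painting-style 5-channel images organised in plates/wells/sites with
  treatments grouped into mechanism (MoA) groups, negative-control wells,
  and per-plate technical batch effects.

Cells are rendered as anisotropic elliptical blobs (nucleus = concentric
smaller ellipse); the protein channel is painted relative to the generated
masks, which makes localization trivially recoverable from the ground truth
and therefore learnable in principle by any representation.  Rendering is
deliberately cheap — no point-spread-function optics, no 3-D structure.

Determinism contract: one root seed; each image draws from an independent
stream derived by hashing ``(seed, image_id)``, so dataset generation is
order-independent and individual images can be regenerated in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, IndexingError, PlacementError
from .image import CELLPAINTING_CHANNELS, HPA_CHANNELS, MultiChannelImage

#: every raster dimension must be divisible by each supported patch size
SUPPORTED_PATCH_SIZES = (4, 8, 16)

LOCALIZATION_CLASSES = ("nuclear", "nucleoplasm", "cytoplasm",
                        "membrane", "punctate", "negative")

#: morphology factors emulate cell-line differences: (major, minor) semi-axes
#: as fractions of min(height, width)
MORPHOLOGY = {
    "round_small": (0.11, 0.10),
    "round_medium": (0.16, 0.14),
    "round_large": (0.21, 0.19),
    "elongated": (0.22, 0.10),
}

#: fraction of cells that re-draw their localization under spatial heterogeneity
SPATIAL_HETEROGENEITY_FRACTION = 0.5

#: the second pattern a spatially heterogeneous condition expresses; fixed per
#: class so pooled single cells of one condition form a two-pattern mixture
ALTERNATE_CLASS = {
    "nuclear": "cytoplasm",
    "nucleoplasm": "cytoplasm",
    "cytoplasm": "nuclear",
    "membrane": "punctate",
    "punctate": "membrane",
    "negative": "punctate",
}
#: per-cell protein gain under intensity heterogeneity: log-uniform over this range
INTENSITY_GAIN_RANGE = (0.25, 1.0)


@dataclass
class SceneSpec:
    height: int = 64
    width: int = 64
    n_channels: int = 4
    n_cells: int = 4
    localization_class: str = "nuclear"
    morphology_factor: str = "round_medium"
    heterogeneity_mode: str = "none"  # none | spatial | intensity
    noise_sd: float = 0.02
    background_level: float = 0.05

    def validate(self) -> None:
        for dim in (self.height, self.width):
            if any(dim % p for p in SUPPORTED_PATCH_SIZES):
                raise ConfigurationError(
                    f"dimension {dim} not divisible by patch sizes {SUPPORTED_PATCH_SIZES}")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        if self.localization_class not in LOCALIZATION_CLASSES:
            raise ConfigurationError(f"unknown localization {self.localization_class}")
        if self.morphology_factor not in MORPHOLOGY:
            raise ConfigurationError(f"unknown morphology {self.morphology_factor}")
        if self.heterogeneity_mode not in ("none", "spatial", "intensity"):
            raise ConfigurationError(f"unknown heterogeneity {self.heterogeneity_mode}")
        if self.n_cells < 0 or self.noise_sd < 0:
            raise ConfigurationError("n_cells and noise_sd must be non-negative")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == 4:
            return HPA_CHANNELS
        if self.n_channels == 5:
            return CELLPAINTING_CHANNELS
        return tuple(f"ch{i}" for i in range(self.n_channels))


@dataclass
class BatchParams:
    """Multiplicative/additive per-channel technical variation."""

    batch_id: str
    per_channel_gain: np.ndarray
    per_channel_offset: np.ndarray

    def __post_init__(self):
        self.per_channel_gain = np.asarray(self.per_channel_gain, dtype=np.float64)
        self.per_channel_offset = np.asarray(self.per_channel_offset, dtype=np.float64)
        if np.any(self.per_channel_gain <= 0):
            raise ConfigurationError("batch gains must be positive")


@dataclass
class GroundTruth:
    cell_masks: np.ndarray      # (H, W) int labels, 0 = background
    nucleus_masks: np.ndarray   # (H, W) int labels matching cell labels
    per_cell_class: list[str]
    scene_labels: set[str] = field(default_factory=set)


def rng_for_image(seed: int, image_id: str) -> np.random.Generator:
    """Independent stream per (root seed, image id); order-independent."""
    tag = zlib.crc32(image_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centres; raise if impossible."""
    a_frac, b_frac = MORPHOLOGY[spec.morphology_factor]
    scale = min(spec.height, spec.width)
    a, b = a_frac * scale, b_frac * scale
    margin = a
    min_sep = 1.7 * b
    centres: list[tuple[float, float]] = []
    tries = 0
    max_tries = 300 * max(spec.n_cells, 1)
    while len(centres) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {spec.n_cells} cells in {spec.height}x{spec.width}")
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2 for y, x in centres):
            centres.append((cy, cx))
    thetas = rng.uniform(0, np.pi, size=spec.n_cells)
    return centres, thetas, a, b


def _elliptic_r2(spec: SceneSpec, centre, theta, a, b) -> np.ndarray:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
    dy, dx = yy - centre[0], xx - centre[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2


def _paint_protein(canvas, r2, nuc_r2, cls, gain, rng, cell_mask):
    if cls == "nuclear":
        canvas += gain * 0.9 * np.exp(-3.0 * nuc_r2) * (nuc_r2 <= 1.0)
    elif cls == "nucleoplasm":
        canvas += gain * 0.75 * (nuc_r2 <= 1.0)
    elif cls == "cytoplasm":
        canvas += gain * 0.7 * ((r2 <= 1.0) & (nuc_r2 > 1.0))
    elif cls == "membrane":
        canvas += gain * 0.85 * ((r2 >= 0.72) & (r2 <= 1.05))
    elif cls == "punctate":
        ys, xs = np.nonzero(cell_mask)
        if len(ys):
            n_dots = 1 + rng.poisson(5)
            picks = rng.integers(0, len(ys), size=n_dots)
            yy, xx = np.mgrid[0:canvas.shape[0], 0:canvas.shape[1]].astype(np.float64)
            for p in picks:
                d2 = (yy - ys[p]) ** 2 + (xx - xs[p]) ** 2
                canvas += gain * 0.9 * np.exp(-d2 / (2 * 1.3 ** 2))
    elif cls == "negative":
        pass


def generate_scene(spec: SceneSpec, seed: int) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one multi-channel scene; deterministic for a given (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    H, W, C = spec.height, spec.width, spec.n_channels
    img = np.zeros((C, H, W), dtype=np.float64)
    cell_masks = np.zeros((H, W), dtype=np.int32)
    nucleus_masks = np.zeros((H, W), dtype=np.int32)
    per_cell_class: list[str] = []

    if spec.n_cells > 0:
        centres, thetas, a, b = _place_cells(spec, rng)

        # spatial heterogeneity: half the cells re-draw to one alternate class
        alt_class = spec.localization_class
        hetero_cells: set[int] = set()
        if spec.heterogeneity_mode == "spatial":
            alt_class = ALTERNATE_CLASS[spec.localization_class]
            flips = rng.uniform(size=spec.n_cells) < SPATIAL_HETEROGENEITY_FRACTION
            hetero_cells = set(np.nonzero(flips)[0].tolist())

        for i, centre in enumerate(centres):
            r2 = _elliptic_r2(spec, centre, thetas[i], a, b)
            nuc_r2 = _elliptic_r2(spec, centre, thetas[i], 0.52 * a, 0.52 * b)
            cell_mask = r2 <= 1.05
            nuc_mask = nuc_r2 <= 1.0
            cell_masks[cell_mask] = i + 1
            nucleus_masks[nuc_mask] = i + 1

            cls = alt_class if i in hetero_cells else spec.localization_class
            per_cell_class.append(cls)
            gain = 1.0
            if spec.heterogeneity_mode == "intensity":
                lo, hi = INTENSITY_GAIN_RANGE
                gain = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

            # structural channels: nucleus dye, then cytoskeletal/organelle dyes
            img[0] += 0.95 * np.exp(-3.0 * nuc_r2) * nuc_mask
            speckle = rng.uniform(0.7, 1.3, size=(H, W))
            for c in range(1, C - 1):
                falloff = 1.2 + 0.5 * c
                img[c] += 0.6 * np.exp(-falloff * r2) * cell_mask * speckle
            _paint_protein(img[C - 1], r2, nuc_r2, cls, gain, rng, cell_mask)

    img += spec.background_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    gt = GroundTruth(cell_masks, nucleus_masks, per_cell_class,
                     scene_labels=set(per_cell_class))
    return MultiChannelImage(img, spec.channel_names), gt


def apply_batch_effect(img: MultiChannelImage, bp: BatchParams) -> MultiChannelImage:
    """out = clip(gain * img + offset, 0, 1), per channel."""
    if bp.per_channel_gain.shape[0] != img.n_channels:
        raise ConfigurationError("batch params do not match channel count")
    gain = bp.per_channel_gain[:, None, None]
    offset = bp.per_channel_offset[:, None, None]
    return MultiChannelImage(np.clip(gain * img.data + offset, 0.0, 1.0), img.channels)


# ---------------------------------------------------------------------------
# dataset generation (plates / wells / sites, index CSV)
# ---------------------------------------------------------------------------

@dataclass
class DatasetPlan:
    """Experiment layout for :func:`generate_dataset`.

    ``class_frequencies`` drives HPA-style per-image localization labels;
    ``treatments`` (name -> MoA group) drives Cell-Painting-style per-well
    phenotypes.  The first ``control_wells_per_plate`` wells of each plate
    are negative controls.
    """

    preset: str = "hpa"  # hpa | cellpainting
    height: int = 64
    width: int = 64
    n_cells: int = 4
    plates: tuple[str, ...] = ("plate1",)
    wells_per_plate: int = 4
    sites_per_well: int = 2
    cell_lines: tuple[str, ...] = ("round_medium",)
    class_frequencies: dict[str, float] | None = None
    treatments: dict[str, str] | None = None
    control_wells_per_plate: int = 0
    heterogeneity_mode: str = "none"
    noise_sd: float = 0.02
    background_level: float = 0.05
    batch_effects: dict[str, BatchParams] | None = None

    @property
    def n_channels(self) -> int:
        return 5 if self.preset == "cellpainting" else 4

    @property
    def n_images(self) -> int:
        return len(self.plates) * self.wells_per_plate * self.sites_per_well

    @classmethod
    def from_yaml(cls, path) -> "DatasetPlan":
        raw = yaml.safe_load(Path(path).read_text())
        if "plates" in raw:
            raw["plates"] = tuple(raw["plates"])
        if "cell_lines" in raw:
            raw["cell_lines"] = tuple(raw["cell_lines"])
        if "batch_effects" in raw and raw["batch_effects"] is not None:
            raw["batch_effects"] = {
                k: BatchParams(k, v["gain"], v["offset"])
                for k, v in raw["batch_effects"].items()}
        return cls(**raw)


def _class_assignment(plan: DatasetPlan, n: int) -> list[str]:
    """Per-image classes honouring the plan frequencies (exact when integral)."""
    freqs = plan.class_frequencies or {"nuclear": 0.5, "cytoplasm": 0.5}
    classes = sorted(freqs)
    raw = np.array([freqs[c] for c in classes], dtype=np.float64)
    raw = raw / raw.sum()
    counts = np.floor(raw * n).astype(int)
    remainder = (raw * n) - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for c, k in zip(classes, counts):
        out.extend([c] * int(k))
    return out


_TREATMENT_PHENOTYPES = ("nuclear", "cytoplasm", "membrane", "punctate", "nucleoplasm")


def generate_dataset(plan: DatasetPlan, out_dir, seed: int):
    """Write per-channel 16-bit TIFFs, an index CSV, and a ground-truth store.

    Returns ``(index DataFrame, {image_id: GroundTruth})``.  The CSV at
    ``out_dir/index.csv`` has one row per image with per-channel paths and
    the metadata columns used throughout the toolkit.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "ground_truth").mkdir(parents=True, exist_ok=True)

    if len(set(plan.plates)) != len(plan.plates):
        raise IndexingError("duplicate plate identifiers in plan")

    n = plan.n_images
    hpa_classes = _class_assignment(plan, n) if plan.preset == "hpa" else None
    treatment_names = sorted(plan.treatments) if plan.treatments else []

    spec_base = dict(height=plan.height, width=plan.width, n_cells=plan.n_cells,
                     heterogeneity_mode=plan.heterogeneity_mode,
                     noise_sd=plan.noise_sd, background_level=plan.background_level)
    channel_names = (CELLPAINTING_CHANNELS if plan.preset == "cellpainting"
                     else HPA_CHANNELS)

    rows, gts = [], {}
    img_idx = 0
    for plate in plan.plates:
        for w in range(plan.wells_per_plate):
            well = f"W{w + 1:02d}"
            is_control = w < plan.control_wells_per_plate
            if plan.preset == "cellpainting":
                if is_control or not treatment_names:
                    treatment, moa, phenotype = "control", "control", "negative"
                else:
                    t = (w - plan.control_wells_per_plate) % len(treatment_names)
                    treatment = treatment_names[t]
                    moa = plan.treatments[treatment]
                    phenotype = _TREATMENT_PHENOTYPES[t % len(_TREATMENT_PHENOTYPES)]
            else:
                treatment, moa = "", ""
            for s in range(plan.sites_per_well):
                image_id = f"{plate}_{well}_s{s + 1}"
                if image_id in gts:
                    raise IndexingError(f"duplicate image_id {image_id}")
                cell_line = plan.cell_lines[img_idx % len(plan.cell_lines)]
                cls = hpa_classes[img_idx] if hpa_classes is not None else phenotype
                spec = SceneSpec(n_channels=plan.n_channels, localization_class=cls,
                                 morphology_factor=cell_line, **spec_base)
                stream = rng_for_image(seed, image_id)
                img, gt = generate_scene(spec, int(stream.integers(0, 2 ** 31)))
                if plan.batch_effects and plate in plan.batch_effects:
                    img = apply_batch_effect(img, plan.batch_effects[plate])

                paths = {}
                for c, ch in enumerate(channel_names):
                    p = out_dir / "images" / f"{image_id}_{ch}.tif"
                    tifffile.imwrite(p, np.round(img.data[c] * 65535).astype(np.uint16))
                    paths[f"path_{ch}"] = str(p)
                tifffile.imwrite(out_dir / "ground_truth" / f"{image_id}_cells.tif",
                                 gt.cell_masks.astype(np.uint16))
                tifffile.imwrite(out_dir / "ground_truth" / f"{image_id}_nuclei.tif",
                                 gt.nucleus_masks.astype(np.uint16))
                (out_dir / "ground_truth" / f"{image_id}.json").write_text(
                    json.dumps({"per_cell_class": gt.per_cell_class,
                                "scene_labels": sorted(gt.scene_labels)}))

                rows.append({"image_id": image_id, **paths, "cell_line": cell_line,
                             "labels": cls, "plate": plate, "well": well,
                             "site": s + 1, "batch": plate, "treatment": treatment,
                             "moa_group": moa, "is_control": bool(is_control)})
                gts[image_id] = gt
                img_idx += 1

    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "index.csv", index=False)
    return index, gts


def load_index_images(index: pd.DataFrame) -> list[MultiChannelImage]:
    """Read the per-channel rasters referenced by an index table."""
    path_cols = [c for c in index.columns if c.startswith("path_")]
    channels = tuple(c[len("path_"):] for c in path_cols)
    out = []
    for _, row in index.iterrows():
        planes = [tifffile.imread(row[c]).astype(np.float64) / 65535.0
                  for c in path_cols]
        out.append(MultiChannelImage(np.stack(planes), channels))
    return out


# ---------------------------------------------------------------------------
# profile-level synthetic data (for batch-correction / MoA protocols)
# ---------------------------------------------------------------------------

def make_profile_dataset(n_moa: int = 4, treatments_per_moa: int = 6,
                         wells_per_treatment: int = 3, n_batches: int = 6,
                         controls_per_batch: int = 12, dim: int = 32,
                         effect_scale: float = 1.0, batch_scale: float = 1.5,
                         noise_scale: float = 0.4, seed: int = 0):
    """Well-level profiles with MoA group structure and per-batch offsets.

    Treatments within a MoA group share a direction in feature space; every
    well additionally receives the additive offset of its batch, emulating
    plate-level technical variation.  Control wells carry the batch offset
    only.  Returns ``(features (n, dim), metadata DataFrame)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    moa_dirs = rng.normal(size=(n_moa, dim))
    moa_dirs /= np.linalg.norm(moa_dirs, axis=1, keepdims=True)
    batch_offsets = batch_scale * rng.normal(size=(n_batches, dim))

    rows, feats = [], []
    for m in range(n_moa):
        for t in range(treatments_per_moa):
            tvec = effect_scale * (moa_dirs[m] + 0.35 * rng.normal(size=dim))
            name = f"moa{m}_trt{t}"
            for w in range(wells_per_treatment):
                # batch membership independent of mechanism: technical, not
                # biological, variation
                batch = int(rng.integers(0, n_batches))
                feats.append(tvec + batch_offsets[batch]
                             + noise_scale * rng.normal(size=dim))
                rows.append({"plate": f"plate{batch}", "batch": f"plate{batch}",
                             "well": f"{name}_w{w}", "treatment": name,
                             "moa_group": f"moa{m}", "is_control": False})
    for b in range(n_batches):
        for w in range(controls_per_batch):
            feats.append(batch_offsets[b] + noise_scale * rng.normal(size=dim))
            rows.append({"plate": f"plate{b}", "batch": f"plate{b}",
                         "well": f"ctrl_b{b}_w{w}", "treatment": "control",
                         "moa_group": "control", "is_control": True})
    return np.asarray(feats), pd.DataFrame(rows)
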