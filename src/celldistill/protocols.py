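"""Desk-scale study protocols bundling the generator, training and evaluation.

These functions define the package's reference experiments on synthetic
scenes: self-distillation pre-training on a 4-class localization corpus with
a frozen-feature kNN read-out, the sphering batch-correction ablation on
profile-level data, and the single-cell heterogeneity analysis.  They are
used by the test suite and by ``scripts/acceptance.py`` so that both run the
same conditions.

Problem sizes are chosen to make each experiment run in minutes on one CPU:
32 x 32 4-channel scenes, a width-32/depth-2 backbone, 2,000 training
images, 700 optimisation steps.
"""

from __future__ import annotations

import numpy as np

from .augment import eval_transform, hpa_preset
from .evaluation import knn_classify
from .features import extract_cell_embeddings
from .image import MultiChannelImage
from .patch_analysis import block_contrast
from .profiling import (ProfileTable, apply_sphering, batch_correction_ablation,
                        cosine_similarity_matrix,
                        mean_within_batch_control_similarity)
from .ssl import TrainConfig, TrainResult, train
from .synth import SceneSpec, generate_scene, make_profile_dataset, rng_for_image
from .vit import BackboneConfig, VisionTransformer

#: the four localization phenotypes of the desk corpus
CORPUS_CLASSES = ("nuclear", "cytoplasm", "membrane", "punctate")

DESK_IMAGE_SIZE = 32
DESK_TRAIN_IMAGES = 2000
DESK_TEST_IMAGES = 400
DESK_STEPS = 700


def make_localization_corpus(n: int, seed: int, tag: str = "train",
                             height: int = DESK_IMAGE_SIZE,
                             width: int = DESK_IMAGE_SIZE, n_cells: int = 2
                             ) -> tuple[list[MultiChannelImage], np.ndarray]:
    """Balanced 4-class corpus of small HPA-style scenes."""
    images, labels = [], []
    for i in range(n):
        cls = CORPUS_CLASSES[i % len(CORPUS_CLASSES)]
        spec = SceneSpec(height=height, width=width, n_cells=n_cells,
                         localization_class=cls)
        stream = rng_for_image(seed, f"{tag}_{i}")
        img, _ = generate_scene(spec, int(stream.integers(0, 2 ** 31)))
        images.append(img)
        labels.append(i % len(CORPUS_CLASSES))
    return images, np.asarray(labels)


def desk_train_config(seed: int, n_steps: int = DESK_STEPS) -> TrainConfig:
    """Reference desk-scale self-distillation configuration."""
    crop, aug = hpa_preset(global_size=DESK_IMAGE_SIZE, local_size=16)
    return TrainConfig(
        backbone=BackboneConfig(n_channels=4, patch_size=8, width=32, depth=2,
                                n_heads=4, image_size=DESK_IMAGE_SIZE),
        crop=crop, aug=aug, n_steps=n_steps, seed=seed)


def knn_accuracy(model: VisionTransformer,
                 train_images: list[MultiChannelImage], train_labels: np.ndarray,
                 test_images: list[MultiChannelImage], test_labels: np.ndarray,
                 crop_size: int = DESK_IMAGE_SIZE, k: int = 20) -> float:
    """Frozen-feature kNN accuracy of a backbone on held-out scenes."""
    tr = model.embed(np.stack([eval_transform(im, crop_size).data
                               for im in train_images])).data
    te = model.embed(np.stack([eval_transform(im, crop_size).data
                               for im in test_images])).data
    pred = knn_classify(tr, train_labels, te, k=k)
    return float(np.mean(pred == test_labels))


def training_signal_experiment(seed: int, n_steps: int = DESK_STEPS,
                               corpus=None) -> dict:
    """Train one self-distilled backbone and score it against random init.

    Returns kNN accuracies of the trained teacher and of an untrained
    backbone of identical architecture, plus the trained model for reuse.
    """
    if corpus is None:
        corpus = default_corpus()
    train_images, train_labels, test_images, test_labels = corpus
    cfg = desk_train_config(seed, n_steps)
    result: TrainResult = train(train_images, cfg)
    random_model = VisionTransformer(cfg.backbone, seed=seed)
    acc_ssl = knn_accuracy(result.teacher, train_images, train_labels,
                           test_images, test_labels)
    acc_random = knn_accuracy(random_model, train_images, train_labels,
                              test_images, test_labels)
    return {"ssl_accuracy": acc_ssl, "random_accuracy": acc_random,
            "gain_points": 100.0 * (acc_ssl - acc_random),
            "model": result.teacher, "trace": result.trace}


def default_corpus(seed: int = 2024):
    """The reference train/test corpus of the desk protocol."""
    train_images, train_labels = make_localization_corpus(
        DESK_TRAIN_IMAGES, seed, "train")
    test_images, test_labels = make_localization_corpus(
        DESK_TEST_IMAGES, seed + 1, "test")
    return train_images, train_labels, test_images, test_labels


def heterogeneity_contrast(model: VisionTransformer, mode: str, scene_seed: int,
                           n_scenes: int = 30, localization: str = "nuclear",
                           crop_size: int = DESK_IMAGE_SIZE) -> float:
    """Block-contrast statistic of pooled single-cell embeddings.

    ``mode`` is the heterogeneity mode of the generated condition; cells are
    rendered one per scene and embedded from exactly-centered crops, the
    single-cell analogue of the similarity-matrix analysis.
    """
    embeddings = []
    for i in range(n_scenes):
        spec = SceneSpec(height=2 * DESK_IMAGE_SIZE, width=2 * DESK_IMAGE_SIZE,
                         n_cells=1, localization_class=localization,
                         heterogeneity_mode=mode)
        img, gt = generate_scene(spec, 1000 * scene_seed + i)
        embeddings.append(extract_cell_embeddings(model, img, gt.cell_masks,
                                                  crop_size))
    pooled = np.concatenate(embeddings)
    return block_contrast(cosine_similarity_matrix(pooled))


def batch_correction_experiment(seed: int, n_repeats: int = 10) -> dict:
    """Sphering ablation on profile-level synthetic Cell-Painting data.

    Returns the MoA-retrieval scores with and without sphering, the percent
    change, and the mean within-batch control similarity before and after
    correction.
    """
    from .evaluation import moa_auprc

    features, meta = make_profile_dataset(seed=seed)
    well_table = ProfileTable(features, meta, "well")

    def evaluator(treatment_table: ProfileTable) -> float:
        return moa_auprc(treatment_table.features,
                         treatment_table.meta["moa_group"].to_numpy(),
                         n_folds=5, n_repeats=n_repeats, seed=seed)["mean_auprc"]

    result = batch_correction_ablation(well_table, evaluator)
    sim_before = mean_within_batch_control_similarity(well_table)
    corrected = ProfileTable(apply_sphering(result["sphering"], features), meta, "well")
    sim_after = mean_within_batch_control_similarity(corrected)
    result.update({"control_similarity_before": sim_before,
                   "control_similarity_after": sim_after})
    return result
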