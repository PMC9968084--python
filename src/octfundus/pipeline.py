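"""End-to-end phantom experiments: synthesize → reconstruct → train → evaluate.

These drivers wire the package's stages together the way the evaluation
protocol prescribes: phantoms are rendered with known en-face vessel
truth, a reconstruction variant is computed and resampled to an isotropic
grid (bicubic for the image, nearest-neighbour for the mask), the
standard conditioning pipeline is applied, patches are sampled from the
training scans, the compact segmenter is trained, and held-out scans are
predicted by sliding-window inference and scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FundusImage, VesselMask
from .evaluation import (
    MetricSet, aggregate_folds, evaluate, make_folds,
)
from .preprocessing import AugmentConfig, PatchSet, extract_patches, preprocess_standard
from .reconstruction import ReconstructionConfig, reconstruct, resample_isotropic, resample_mask_isotropic
from .segmentation import ModelConfig, binarize, build_model, predict_image, train
from .synthetic import Phantom, PhantomConfig, phantom_cohort


@dataclass
class ExperimentResult:
    """Held-out metrics of one train/test run plus training history."""

    per_image: list[MetricSet]
    mean: MetricSet
    history: object
    variant: str
    n_train: int
    n_test: int


def prepare_fundus(phantom: Phantom, variant: str = "P3",
                   resample: bool = True,
                   preprocess: bool = True) -> tuple[FundusImage, VesselMask]:
    """Reconstruct, resample to isotropic pitch and condition one phantom."""
    recon = reconstruct(phantom.volume, phantom.surfaces,
                        ReconstructionConfig(variant=variant))
    mask_px = phantom.vessel_mask.pixels
    if resample:
        pitch = recon.pixel_pitch_mm
        recon = resample_isotropic(recon)
        mask_px = resample_mask_isotropic(mask_px, pitch)
    if preprocess:
        recon = preprocess_standard(recon)
    return recon, VesselMask(mask_px)


def _pool_patches(images: list[FundusImage], masks: list[VesselMask],
                  n_total: int, size: int, seed: int) -> PatchSet:
    per = [n_total // len(images)] * len(images)
    for i in range(n_total - sum(per)):
        per[i] += 1
    parts = [
        extract_patches(img, msk, k, size, seed=seed + i)
        for i, (img, msk, k) in enumerate(zip(images, masks, per))
    ]
    return PatchSet(
        images=np.concatenate([p.images for p in parts]),
        masks=np.concatenate([p.masks for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        size=size, seed=seed,
    )


def run_phantom_experiment(
    variant: str = "P3",
    n_volumes: int = 8,
    n_test: int = 2,
    seed: int = 0,
    phantom_config: PhantomConfig | None = None,
    model_config: ModelConfig | None = None,
    n_patches: int = 2000,
    patch_size: int = 48,
    stride: int | None = None,
) -> ExperimentResult:
    """Train on a phantom cohort and score the held-out scans.

    Defaults follow the desk-scale protocol: 8 small-preset phantoms, the
    last ``n_test`` held out, a depth-3 / 8-filter model trained 10
    epochs on 2,000 48×48 patches with right-angle-rotation/flip
    augmentation, sliding-window prediction at half-patch stride, and
    per-image accuracy/sensitivity/specificity/precision/F1/AUC.
    """
    phantom_config = phantom_config or PhantomConfig.small()
    model_config = model_config or ModelConfig(
        depth=3, base_filters=8, epochs=10, batch_size=32,
        optimizer="adam", lr=1e-3, loss="bce", val_split=0.1,
        augment_preset="frunet", seed=seed,
    )
    phantoms = phantom_cohort(phantom_config, n_volumes, seed)
    pairs = [prepare_fundus(ph, variant) for ph in phantoms]
    train_pairs, test_pairs = pairs[:-n_test], pairs[-n_test:]

    patchset = _pool_patches(
        [img for img, _ in train_pairs], [msk for _, msk in train_pairs],
        n_patches, patch_size, seed=seed,
    )
    model = build_model(model_config)
    model, history = train(model, patchset, model_config,
                           AugmentConfig(preset=model_config.augment_preset, seed=seed))

    per_image = []
    for img, msk in test_pairs:
        prob = predict_image(model, img, patch_size=patch_size, stride=stride)
        per_image.append(evaluate(binarize(prob, 0.5), msk, prob=prob))
    mean, _ = aggregate_folds(per_image)
    return ExperimentResult(per_image, mean, history, variant,
                            len(train_pairs), len(test_pairs))


def cross_validate_phantoms(
    variant: str = "P3",
    n_volumes: int = 8,
    n_folds: int = 4,
    seed: int = 0,
    phantom_config: PhantomConfig | None = None,
    model_config: ModelConfig | None = None,
    n_patches: int = 2000,
    patch_size: int = 48,
) -> tuple[MetricSet, list[dict]]:
    """Full k-fold cross-validation over a phantom cohort.

    Each fold trains a fresh model on the training scans and scores the
    fold's test scans; fold-level metric means are averaged unweighted.
    """
    phantom_config = phantom_config or PhantomConfig.small()
    phantoms = phantom_cohort(phantom_config, n_volumes, seed)
    pairs = [prepare_fundus(ph, variant) for ph in phantoms]
    split = make_folds(list(range(n_volumes)), n_folds, seed=seed)
    fold_means = []
    for fold in split:
        mc = model_config or ModelConfig(
            depth=3, base_filters=8, epochs=10, batch_size=32,
            optimizer="adam", lr=1e-3, loss="bce", val_split=0.1,
            augment_preset="frunet", seed=seed,
        )
        patchset = _pool_patches(
            [pairs[i][0] for i in fold["train"]],
            [pairs[i][1] for i in fold["train"]],
            n_patches, patch_size, seed=seed,
        )
        model = build_model(mc)
        model, _ = train(model, patchset, mc,
                         AugmentConfig(preset=mc.augment_preset, seed=seed))
        per_image = []
        for i in fold["test"]:
            img, msk = pairs[i]
            prob = predict_image(model, img, patch_size=patch_size)
            per_image.append(evaluate(binarize(prob, 0.5), msk, prob=prob))
        fold_mean, _ = aggregate_folds(per_image)
        fold_means.append(fold_mean)
    return aggregate_folds(fold_means)
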