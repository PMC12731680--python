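"""End-to-end benchmark experiments: selection, training, model comparison.

These routines chain the pipeline stages the way the full study runs
them: generate (or load) egg scenes, smooth spectra, select wavelengths
on labelled training pixels, train segmentation models on the selected
bands and report pooled test metrics. They back both the CLI ``compare``
subcommand and the acceptance checks.

Desk-scale defaults (100 eggs of 64 x 64 pixels, 8 channels at the first
network stage, a few hundred training crops) keep a full four-model
comparison tractable on one CPU core while preserving the qualitative
structure of the full-size task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_selection import BandSubset, CarsConfig, apply_subset, cars_select
from .core import SpectralCube
from .errors import ParameterError
from .io_envi import log
from .preprocess import (SpectraMatrix, extract_labeled_pixels, msc_correct,
                         preprocess_cube)
from .nn import NetworkConfig, build_model
from .synthetic_data import SyntheticSceneParams, build_benchmark
from .train_eval import TrainConfig, evaluate_model, split_dataset, train

BENCHMARK_N_EGGS = 100


@dataclass
class ComparisonConfig:
    """Settings for the scaled-down model-comparison experiment."""

    n_eggs: int = BENCHMARK_N_EGGS
    kinds: tuple = ("cracknet3d", "cnn3d", "cnn2d", "cnn1d")
    seeds: tuple = (0, 1, 2)
    epochs: int = 12
    batch_size: int = 8
    crops_per_image: int = 2
    max_batches_per_epoch: int | None = None
    learning_rate: float = 5e-3
    focal_alpha: float = 0.7
    dice_weight: float = 0.75
    crop_size: int = 24
    base_channels: int = 8
    selection_pixels_per_class: int = 40
    selection_eggs: int = 20
    min_bands: int = 12    # keep a usable spectral axis for the 3-D models
    max_bands: int = 16    # ... at a cost comparable to the ~15-band scale
    data_seed: int = 0


def selection_matrix(scenes, n_eggs: int = 20, n_per_class: int = 40,
                     seed: int = 0, apply_msc: bool = True) -> SpectraMatrix:
    """Pool labelled pixel spectra from cracked scenes for band selection.

    Spectra are scatter-corrected (MSC against the pooled mean) before
    selection; cracked scenes only, since selection needs both classes.
    """
    xs, ys, grid = [], [], None
    used = 0
    for cube, mask in scenes:
        if mask.crack_pixel_count == 0:
            continue
        m = extract_labeled_pixels(cube, mask, n_per_class=n_per_class,
                                   seed=seed + used)
        xs.append(m.X)
        ys.append(m.y)
        grid = m.band_grid
        used += 1
        if used >= n_eggs:
            break
    if not xs:
        raise ParameterError("no cracked scenes available for band selection")
    X = np.vstack(xs)
    y = np.concatenate(ys)
    if apply_msc:
        X, _ = msc_correct(X)
    return SpectraMatrix(X=X, y=y, band_grid=grid)


def select_benchmark_bands(scenes, cfg: ComparisonConfig | None = None,
                           seed: int = 0) -> BandSubset:
    """CARS wavelength selection on pooled training-pixel spectra."""
    cfg = cfg or ComparisonConfig()
    M = selection_matrix(scenes, n_eggs=cfg.selection_eggs,
                         n_per_class=cfg.selection_pixels_per_class,
                         seed=seed)
    return cars_select(M, CarsConfig(seed=seed, mc_draws=10,
                                     min_bands=cfg.min_bands,
                                     max_bands=cfg.max_bands))


def run_model_comparison(cfg: ComparisonConfig | None = None,
                         scenes=None) -> pd.DataFrame:
    """Train every model kind over several seeds; pooled test metrics.

    Pipeline per run: SG-smoothed scenes -> CARS band subset frozen from
    the training split -> seeded training -> pooled test-set metrics.
    Returns one row per (kind, seed) with F1/IoU/precision/recall.
    """
    cfg = cfg or ComparisonConfig()
    if scenes is None:
        scenes, _ = build_benchmark(cfg.n_eggs, seed=cfg.data_seed)
    # Spectral denoising; scatter correction stays in the chemometric step.
    smoothed = [(preprocess_cube(cube, msc_enabled=False)[0], mask)
                for cube, mask in scenes]

    ids = list(range(len(smoothed)))
    train_ids, val_ids, test_ids = split_dataset(ids, (8, 1, 1),
                                                 seed=cfg.data_seed)
    train_scenes = [smoothed[i] for i in train_ids]
    subset = select_benchmark_bands(train_scenes, cfg, seed=cfg.data_seed)
    log.info("comparison: %d bands selected by CARS", subset.n_bands)

    def reduce(split):
        return [(apply_subset(smoothed[i][0], subset), smoothed[i][1])
                for i in split]

    tr, va, te = reduce(train_ids), reduce(val_ids), reduce(test_ids)

    records = []
    for kind in cfg.kinds:
        for seed in cfg.seeds:
            net_cfg = NetworkConfig(in_bands=subset.n_bands,
                                    base_channels=cfg.base_channels)
            model = build_model(kind, net_cfg, seed=seed)
            tc = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                             learning_rate=cfg.learning_rate,
                             focal_alpha=cfg.focal_alpha,
                             dice_weight=cfg.dice_weight,
                             crop_size=cfg.crop_size,
                             crops_per_image=cfg.crops_per_image,
                             patience=cfg.epochs + 1,
                             scheduler_t0=cfg.epochs,
                             max_batches_per_epoch=cfg.max_batches_per_epoch,
                             seed=seed)
            # Validation monitoring on a fixed subset keeps epochs cheap;
            # the full validation split then picks the decision threshold.
            model, history = train(model, tr, va[:5], tc)
            threshold = tune_threshold(model, va)
            report, _ = evaluate_model(model, te, threshold=threshold)
            records.append({
                "kind": kind, "seed": seed, "f1": report.f1,
                "iou": report.iou, "precision": report.precision,
                "recall": report.recall, "threshold": threshold,
                "final_val_f1": history["val_f1"][-1],
            })
            log.info("comparison: %s seed %d test F1 %.3f",
                     kind, seed, report.f1)
    return pd.DataFrame.from_records(records)


def tune_threshold(model, val_set, grid=None) -> float:
    """Pick the binarization threshold maximizing pooled validation F1."""
    from .train_eval import (ConfusionCounts, as_pairs, compute_metrics,
                             confusion_counts, _full_image_prob)
    if grid is None:
        grid = np.concatenate([np.arange(0.2, 0.9, 0.05),
                               [0.9, 0.93, 0.96, 0.98]])
    probs = [(_full_image_prob(model, d), l) for d, l in as_pairs(val_set)]

    def pooled_f1(th):
        c = ConfusionCounts(0, 0, 0, 0)
        for p, l in probs:
            c = c + confusion_counts((p > th).astype(np.uint8),
                                     l.astype(np.uint8))
        return compute_metrics(c).f1

    return float(max(grid, key=pooled_f1))


def mean_f1_by_kind(table: pd.DataFrame) -> dict[str, float]:
    return table.groupby("kind")["f1"].mean().to_dict()
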