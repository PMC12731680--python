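"""Train a small crack segmenter end to end on a tiny synthetic benchmark.

Scaled far down (12 eggs, 40 bands, a few epochs) so it finishes in a
couple of minutes on one core; see experiments.py for the full setup.
"""

import numpy as np

from crackspec import (NetworkConfig, SyntheticSceneParams, TrainConfig,
                       WavelengthGrid, build_benchmark, build_model,
                       evaluate_model, split_dataset, train)
from crackspec.experiments import select_benchmark_bands, ComparisonConfig
from crackspec.band_selection import apply_subset
from crackspec.preprocess import preprocess_cube

grid = WavelengthGrid(np.linspace(1000, 2500, 40))
template = SyntheticSceneParams(rows=32, cols=32, grid=grid)
scenes, manifest = build_benchmark(12, template, seed=5)
scenes = [(preprocess_cube(c, msc_enabled=False)[0], m) for c, m in scenes]

tr, va, te = split_dataset(list(range(12)), (8, 1, 1), seed=5)
subset = select_benchmark_bands([scenes[i] for i in tr],
                                ComparisonConfig(min_bands=6, max_bands=12),
                                seed=5)
print(f"CARS kept {subset.n_bands} of 40 bands")

reduce = lambda ids: [(apply_subset(scenes[i][0], subset), scenes[i][1])
                      for i in ids]
model = build_model("cracknet3d",
                    NetworkConfig(in_bands=subset.n_bands, encoder_units=2,
                                  base_channels=6), seed=0)
tc = TrainConfig(epochs=10, batch_size=4, learning_rate=5e-3, crop_size=None,
                 crops_per_image=3, dice_weight=0.75,
                 patience=11, scheduler_t0=10, seed=0)
model, history = train(model, reduce(tr), reduce(va), tc)
report, _ = evaluate_model(model, reduce(te))
print(f"val F1 trace: {[round(v, 2) for v in history['val_f1']]}")
print(f"held-out egg: F1 {report.f1:.2f}, IoU {report.iou:.2f}, "
      f"precision {report.precision:.2f}, recall {report.recall:.2f}")

# Even this miniature run (60 gradient steps, 9 training eggs) finds
# most of the crack with high precision; the standard benchmark
# (100 eggs, 64x64, 273 bands, longer training) reaches F1 ~0.75 and is
# exercised by scripts/acceptance.py.
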