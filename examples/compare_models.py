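"""Compare the four model kinds on a reduced synthetic benchmark.

Spatial-spectral models should beat the spatial-only (2D) and
spectral-only (1D) baselines, mirroring the design rationale of joint
modeling. Uses a small benchmark and one seed to stay quick; the
standard comparison (100 eggs, 3 seeds) runs in the acceptance suite.
"""

from crackspec.experiments import (ComparisonConfig, mean_f1_by_kind,
                                   run_model_comparison)

cfg = ComparisonConfig(n_eggs=30, seeds=(0,), epochs=8,
                       max_batches_per_epoch=6)
table = run_model_comparison(cfg)
print(table[["kind", "seed", "f1", "precision", "recall"]].to_string())
print()
for kind, f1 in sorted(mean_f1_by_kind(table).items(),
                       key=lambda kv: -kv[1]):
    print(f"{kind:10s} mean F1 {f1:.3f}")

# Expect the residual/attention 3-D network and the plain 3-D baseline
# at the top: crack-vs-spot discrimination needs spectral AND spatial
# context at once.
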