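"""Segmentation networks: the 3-D residual/attention U-Net and baselines.

Four model kinds share one training interface:

* ``cracknet3d`` — U-Net-style encoder-decoder over the spatial-spectral
  cube; each encoder unit is a 3-D residual block, a SimAM attention
  module and a spatial 2x2 max-pool; the decoder mirrors with
  nearest-neighbour upsampling and skip concatenation; a head spanning
  the full remaining spectral depth collapses to a 2-D sigmoid
  probability map.
* ``cnn3d`` — identical topology with plain double-conv blocks and no
  attention (the ablation baseline).
* ``cnn2d`` — the same U-Net on the spectrally averaged single image
  (spatial context only).
* ``cnn1d`` — a per-pixel convolutional classifier over the band axis
  (spectral context only; invariant to spatial permutation).

Pooling is spatial-only (1, 2, 2): with ~15 input bands, halving the
spectral axis at every unit would annihilate it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..band_selection import BandSubset, apply_subset
from ..core import CrackMask, SpectralCube
from ..errors import ParameterError
from .attention import SimAM3d, DEFAULT_LAMBDA
from .blocks import ConvBlock3d, ResBlock3d
from .layers import (BatchNorm3d, Conv3d, Layer, MaxPool3d, Parameter, ReLU,
                     Sigmoid, SpectralCollapse, Upsample3d)

MODEL_KINDS = ("cracknet3d", "cnn3d", "cnn2d", "cnn1d")


@dataclass
class NetworkConfig:
    in_bands: int = 15
    encoder_units: int = 3
    base_channels: int = 16
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: tuple[int, int, int] = (1, 2, 2)
    simam_lambda: float = DEFAULT_LAMBDA
    attention_variant: str = "direct"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.encoder_units < 1:
            raise ParameterError("encoder_units must be >= 1")
        if not (0 < self.threshold < 1):
            raise ParameterError("threshold must be in (0, 1)")
        if any(k % 2 == 0 for k in self.kernel):
            raise ParameterError("kernel entries must be odd")
        self.kernel = tuple(self.kernel)
        self.pool = tuple(self.pool)

    @property
    def spatial_divisor(self) -> int:
        return self.pool[1] ** self.encoder_units


class _BaseModel:
    """Shared bookkeeping: parameter traversal, input preparation."""

    kind: str = ""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        # Input standardization (set by the trainer, bundled in checkpoints).
        self.input_mean = 0.0
        self.input_std = 1.0

    def layers(self) -> list[Layer]:
        found: list[Layer] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Layer):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    found.append(obj)
                    for v in vars(obj).values():
                        visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        for v in vars(self).values():
            visit(v)
        return found

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for layer in self.layers():
            params.extend(layer.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def prepare_input(self, cubes: np.ndarray) -> np.ndarray:
        """Map a ``(N, H, W, D)`` stack of cube patches to a network input."""
        x = np.ascontiguousarray(cubes.transpose(0, 3, 1, 2), dtype=np.float32)
        x = (x - np.float32(self.input_mean)) / np.float32(self.input_std)
        x = x[:, None]  # (N, 1, D, H, W)
        if self.kind == "cnn2d":
            x = x.mean(axis=2, keepdims=True)
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> None:
        raise NotImplementedError


class UNet3D(_BaseModel):
    """Encoder-decoder over (N, 1, D, H, W) with skip connections."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0,
                 residual: bool = True, use_simam: bool = True,
                 kind: str = "cracknet3d"):
        super().__init__(cfg, seed)
        self.kind = kind
        rng = np.random.default_rng(seed)
        block_cls = ResBlock3d if residual else ConvBlock3d
        kernel = (1, cfg.kernel[1], cfg.kernel[2]) if kind == "cnn2d" \
            else cfg.kernel

        def attn():
            return SimAM3d(cfg.simam_lambda, cfg.attention_variant) \
                if use_simam else None

        u = cfg.encoder_units
        chans = [cfg.base_channels * 2 ** i for i in range(u)]

        self.enc_blocks, self.enc_attn, self.pools = [], [], []
        in_ch = 1
        for c in chans:
            self.enc_blocks.append(block_cls(in_ch, c, kernel, rng=rng))
            self.enc_attn.append(attn())
            self.pools.append(MaxPool3d(cfg.pool))
            in_ch = c

        self.bottleneck = block_cls(chans[-1], chans[-1], kernel, rng=rng)
        self.bottleneck_attn = attn()

        self.ups, self.dec_blocks, self.dec_attn = [], [], []
        cur = chans[-1]
        for i in reversed(range(u)):
            out_ch = chans[max(i - 1, 0)]
            self.ups.append(Upsample3d(cfg.pool))
            self.dec_blocks.append(block_cls(cur + chans[i], out_ch,
                                             kernel, rng=rng))
            self.dec_attn.append(attn())
            cur = out_ch

        depth = 1 if kind == "cnn2d" else cfg.in_bands
        self.head = SpectralCollapse(cur, depth, rng=rng)
        self.out_sigmoid = Sigmoid()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        div = self.cfg.spatial_divisor
        if x.shape[3] % div or x.shape[4] % div:
            raise ParameterError(
                f"spatial dims {x.shape[3:]} must divide {div}; pad first")
        skips = []
        h = x
        for block, attn, pool in zip(self.enc_blocks, self.enc_attn, self.pools):
            h = block.forward(h, training)
            if attn is not None:
                h = attn.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        if self.bottleneck_attn is not None:
            h = self.bottleneck_attn.forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, block, attn, skip in zip(self.ups, self.dec_blocks,
                                         self.dec_attn, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, training)
            if attn is not None:
                h = attn.forward(h, training)
        logits = self.head.forward(h, training)
        return self.out_sigmoid.forward(logits, training)

    def backward(self, grad: np.ndarray) -> None:
        g = self.out_sigmoid.backward(grad)
        g = self.head.backward(g)
        skip_grads = []
        n_units = len(self.dec_blocks)
        for i in reversed(range(n_units)):
            if self.dec_attn[i] is not None:
                g = self.dec_attn[i].backward(g)
            g = self.dec_blocks[i].backward(g)
            skip_ch = self._skip_channels[n_units - 1 - i]
            g, g_skip = g[:, :-skip_ch], g[:, -skip_ch:]
            skip_grads.append(np.ascontiguousarray(g_skip))
            g = self.ups[i].backward(np.ascontiguousarray(g))
        # skip_grads[j] belongs to encoder unit j (shallowest appended first).
        if self.bottleneck_attn is not None:
            g = self.bottleneck_attn.backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(len(self.enc_blocks))):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            if self.enc_attn[i] is not None:
                g = self.enc_attn[i].backward(g)
            g = self.enc_blocks[i].backward(g)


class PixelSpectralNet(_BaseModel):
    """Per-pixel 1-D convolutional classifier over the band axis."""

    kind = "cnn1d"

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__(cfg, seed)
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        k = (cfg.kernel[0], 1, 1)  # spectral-only kernels: no spatial context
        self.seq = [
            Conv3d(1, c, k, rng=rng), BatchNorm3d(c), ReLU(),
            Conv3d(c, 2 * c, k, rng=rng), BatchNorm3d(2 * c), ReLU(),
        ]
        self.head = SpectralCollapse(2 * c, cfg.in_bands, rng=rng)
        self.out_sigmoid = Sigmoid()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.seq:
            h = layer.forward(h, training)
        logits = self.head.forward(h, training)
        return self.out_sigmoid.forward(logits, training)

    def backward(self, grad: np.ndarray) -> None:
        g = self.out_sigmoid.backward(grad)
        g = self.head.backward(g)
        for layer in reversed(self.seq):
            g = layer.backward(g)


def build_model(kind: str, cfg: NetworkConfig | None = None, seed: int = 0):
    """Construct a model of the requested kind with seeded initialization."""
    cfg = cfg or NetworkConfig()
    if kind == "cracknet3d":
        return UNet3D(cfg, seed, residual=True, use_simam=True, kind=kind)
    if kind == "cnn3d":
        return UNet3D(cfg, seed, residual=False, use_simam=False, kind=kind)
    if kind == "cnn2d":
        return UNet3D(cfg, seed, residual=False, use_simam=False, kind=kind)
    if kind == "cnn1d":
        return PixelSpectralNet(cfg, seed)
    raise ParameterError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def count_trainable_parameters(module) -> int:
    """Exact count of trainable scalars in a model or a single layer."""
    if isinstance(module, Layer):
        params = _walk_params(module)
    else:
        params = module.parameters()
    seen, total = set(), 0
    for p in params:
        if id(p) not in seen:
            seen.add(id(p))
            total += p.size
    return total


def _walk_params(layer: Layer) -> list[Parameter]:
    params = list(layer.parameters())
    for v in vars(layer).values():
        if isinstance(v, Layer):
            params.extend(_walk_params(v))
    return params


def _reflect_pad_hw(data: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple]:
    h, w = data.shape[:2]
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph or pw:
        data = np.pad(data, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return data, (h, w)


def predict_mask(model, cube: SpectralCube, subset: BandSubset | None = None,
                 threshold: float | None = None, tile: int | None = None
                 ) -> tuple[np.ndarray, CrackMask]:
    """Run inference on a cube, returning (probability map, binary mask).

    When ``tile`` is given the cube is processed in independent
    non-overlapping spatial tiles and the probability maps stitched.
    Spatial dims are reflection-padded to the model's pooling divisor and
    cropped back. Binarization is strict: mask = probability > threshold.
    """
    if subset is not None:
        cube = apply_subset(cube, subset)
    if model.kind != "cnn2d" and cube.bands != model.cfg.in_bands:
        raise ParameterError(
            f"cube has {cube.bands} bands, model expects {model.cfg.in_bands}")
    if threshold is None:
        threshold = model.cfg.threshold

    div = getattr(model.cfg, "spatial_divisor", 1)
    if isinstance(model, PixelSpectralNet):
        div = 1

    def run(patch: np.ndarray) -> np.ndarray:
        padded, (h, w) = _reflect_pad_hw(patch, div)
        x = model.prepare_input(padded[None])
        prob = model.forward(x, training=False)[0]
        return prob[:h, :w]

    data = cube.data
    rows, cols = data.shape[:2]
    if tile is None or (rows <= tile and cols <= tile):
        prob = run(data)
    else:
        prob = np.zeros((rows, cols), dtype=np.float32)
        for r0 in range(0, rows, tile):
            for c0 in range(0, cols, tile):
                patch = data[r0:r0 + tile, c0:c0 + tile]
                prob[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] = run(patch)
    prob = np.clip(prob, 0.0, 1.0)
    return prob, CrackMask((prob > threshold).astype(np.uint8))


def save_checkpoint(model, path, band_subset: BandSubset | None = None,
                    msc_reference: np.ndarray | None = None) -> Path:
    """Bundle weights, config, normalization stats and the band subset."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:04d}"] = p.data
    for i, layer in enumerate(model.layers()):
        if isinstance(layer, BatchNorm3d):
            arrays[f"bn_{i:04d}_mean"] = layer.running_mean
            arrays[f"bn_{i:04d}_var"] = layer.running_var
    meta = {
        "kind": model.kind,
        "seed": model.seed,
        "config": asdict(model.cfg),
        "input_mean": float(model.input_mean),
        "input_std": float(model.input_std),
    }
    if band_subset is not None:
        meta["band_indices"] = band_subset.indices.tolist()
        meta["band_method"] = band_subset.method
    if msc_reference is not None:
        arrays["msc_reference"] = np.asarray(msc_reference)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path):
    """Restore a model (and its band subset, if bundled) from disk."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg_d = meta["config"]
        cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in cfg_d.items()})
        model = build_model(meta["kind"], cfg, seed=meta["seed"])
        model.input_mean = meta["input_mean"]
        model.input_std = meta["input_std"]
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i:04d}"]
        for i, layer in enumerate(model.layers()):
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = data[f"bn_{i:04d}_mean"]
                layer.running_var[...] = data[f"bn_{i:04d}_var"]
        subset = None
        if "band_indices" in meta:
            subset = BandSubset(indices=np.asarray(meta["band_indices"]),
                                method=meta.get("band_method", "full"))
        msc_ref = data["msc_reference"] if "msc_reference" in data else None
    return model, subset, msc_ref
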