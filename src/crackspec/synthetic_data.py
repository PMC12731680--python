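"""Seeded synthetic SWIR egg scenes with ground-truth crack masks.

The generator is phenomenological: smooth per-color reflectance
baselines carry Gaussian absorption valleys at the 1450 and 1940 nm
water-overtone bands and a broad shallow protein feature across
2100-2300 nm. Cracked shell shows a multiplicative reflectance drop and
deepened water valleys (exposed-membrane moisture), so crack pixels lie
below intact shell at every band. Speckle confounders perturb broadband
intensity only — their relative valley depths stay intact — so spectral
rather than spatial cues separate them from cracks. Scenes add
limb-darkened elliptical egg geometry over a dark-velvet background and
Gaussian sensor noise, and are bit-reproducible under a seed.

Crack severity derives from a slider-impact model: a mass released from
height h arrives at v = sqrt(2 g h) with energy E = m g h, mapped to a
saturating severity in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CrackMask, SpectralCube, WavelengthGrid
from .errors import ParameterError
from .io_envi import write_envi, write_mask
from .preprocess import SpectraMatrix

SHELL_COLORS = ("white", "brown", "speckled")
CRACK_TYPES = ("none", "linear", "star", "hairline")

# Per-color mean SWIR reflectance level (placeholder magnitudes).
_BASE_LEVEL = {"white": 0.78, "brown": 0.55, "speckled": 0.66}

# Absorption features: (center nm, sigma nm, fractional depth).
_WATER_DIPS = ((1450.0, 40.0, 0.16), (1940.0, 55.0, 0.22))
_PROTEIN_DIP = (2200.0, 90.0, 0.06)

_CRACK_REFLECTANCE_FACTOR = 0.78   # broadband drop on cracked shell
_CRACK_DIP_DEEPENING = 1.35        # water valleys deepen on cracked shell
_HAIRLINE_BLEND = 0.5              # hairline cracks are low-contrast


@dataclass
class SyntheticSceneParams:
    rows: int = 64
    cols: int = 64
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.default_swir)
    shell_color: str = "white"
    crack_type: str = "linear"
    severity: float = 0.6
    spot_density: float = 3.0      # expected confounder spots per scene
    texture_sd: float = 0.03       # shell-texture broadband intensity spread
    dip_jitter_sd: float = 0.15    # per-pixel water-valley depth variability
    noise_sd: float = 0.02         # sensor noise, reflectance units
    background_level: float = 0.05  # dark-velvet stage reflectance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 16 or self.cols < 16:
            raise ParameterError("scene must be at least 16 x 16 pixels")
        if not (0.0 <= self.severity <= 1.0):
            raise ParameterError("severity must lie in [0, 1]")
        if self.shell_color not in SHELL_COLORS:
            raise ParameterError(f"unknown shell color {self.shell_color!r}")
        if self.crack_type not in CRACK_TYPES:
            raise ParameterError(f"unknown crack type {self.crack_type!r}")


@dataclass
class ImpactModel:
    """Slider on a smooth incline: frictionless release from ``height_m``."""

    mass_kg: float = 0.150
    height_m: float = 0.125
    g: float = 9.8

    def __post_init__(self) -> None:
        if self.mass_kg <= 0 or self.height_m <= 0 or self.g <= 0:
            raise ParameterError("mass, height and g must all be positive")


def impact_kinematics(m: ImpactModel) -> tuple[float, float]:
    """Impact velocity (m/s) and kinetic energy (J) of the slider."""
    velocity = math.sqrt(2.0 * m.g * m.height_m)
    energy = m.mass_kg * m.g * m.height_m
    return velocity, energy


def severity_from_energy(energy_j: float, scale: float = 0.15,
                         gain: float = 1.0) -> float:
    """Monotone saturating map from impact energy to crack severity."""
    if energy_j < 0:
        raise ParameterError("energy must be non-negative")
    return float(np.clip(gain * (1.0 - math.exp(-energy_j / scale)), 0.0, 1.0))


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _spectrum_components(color: str, grid: WavelengthGrid,
                         rng: np.random.Generator):
    """Scene-level spectral building blocks, jittered per scene.

    Returns ``(base, water_dip, protein_dip)`` such that an intact
    spectrum with water-valley depth factor ``j`` is
    ``base * (1 − j·water_dip − protein_dip)``.
    """
    wl = grid.centers_nm
    level = _BASE_LEVEL[color] * (1.0 + 0.03 * rng.standard_normal())
    slope = 0.08 * (1.0 + 0.2 * rng.standard_normal())
    u = (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)
    base = level * (1.0 - slope * u + 0.02 * u * (1 - u))

    water = np.zeros_like(wl)
    for center, sigma, depth in _WATER_DIPS:
        d = depth * (1.0 + 0.1 * rng.standard_normal())
        water += d * _gauss(wl, center, sigma)
    center, sigma, depth = _PROTEIN_DIP
    protein = depth * _gauss(wl, center, sigma)
    return base, water, protein


def _spectrum_pair(color: str, grid: WavelengthGrid,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Intact and cracked shell spectra sharing one jittered baseline."""
    base, water, protein = _spectrum_components(color, grid, rng)
    intact = base * (1.0 - water - protein)
    crack = _CRACK_REFLECTANCE_FACTOR * base * (
        1.0 - _CRACK_DIP_DEEPENING * water - protein)
    return np.clip(intact, 0.0, None), np.clip(crack, 0.0, None)


def shell_spectrum(color: str, state: str = "intact",
                   grid: WavelengthGrid | None = None,
                   seed: int = 0) -> np.ndarray:
    """One seeded shell spectrum for the given color and crack state."""
    if state not in ("intact", "crack"):
        raise ParameterError(f"unknown shell state {state!r}")
    grid = grid or WavelengthGrid.default_swir()
    intact, crack = _spectrum_pair(color, grid, np.random.default_rng(seed))
    return intact if state == "intact" else crack


def _draw_polyline(mask: np.ndarray, inside: np.ndarray, r: float, c: float,
                   angle: float, length: int, rng: np.random.Generator) -> None:
    rows, cols = mask.shape
    for _ in range(length):
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < rows and 0 <= ci < cols and inside[ri, ci]:
            mask[ri, ci] = 1
        angle += 0.25 * rng.standard_normal()
        r += math.sin(angle)
        c += math.cos(angle)


def _dilate(mask: np.ndarray, inside: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out & inside


def _crack_mask(p: SyntheticSceneParams, inside: np.ndarray,
                rng: np.random.Generator, stretch: float = 1.0) -> np.ndarray:
    rows, cols = inside.shape
    mask = np.zeros((rows, cols), dtype=np.uint8)
    if p.crack_type == "none":
        return mask
    interior = np.argwhere(inside)
    r0, c0 = interior[rng.integers(len(interior))]
    base_len = max(12, int(stretch * p.severity * 0.9 * min(rows, cols)))
    if p.crack_type == "star":
        n_arms = int(rng.integers(3, 7))
        for _ in range(n_arms):
            _draw_polyline(mask, inside, float(r0), float(c0),
                           rng.uniform(0, 2 * math.pi), max(4, base_len // 2),
                           rng)
    else:  # linear or hairline
        _draw_polyline(mask, inside, float(r0), float(c0),
                       rng.uniform(0, 2 * math.pi), base_len, rng)
    if p.crack_type == "linear" and p.severity > 0.4:
        mask = _dilate(mask, inside)  # severe visible cracks widen to 2-3 px
    return mask


def generate_egg_cube(p: SyntheticSceneParams
                      ) -> tuple[SpectralCube, CrackMask]:
    """Render one egg scene and its exact crack mask, seeded by ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    rows, cols, bands = p.rows, p.cols, p.grid.count

    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a = 0.46 * rows * (1.0 + 0.05 * rng.standard_normal())
    b = 0.36 * cols * (1.0 + 0.05 * rng.standard_normal())
    rho2 = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2
    inside = rho2 <= 1.0
    # Curved-shell illumination falloff toward the limb.
    illum = np.where(inside, 0.55 + 0.45 * np.sqrt(np.clip(1 - rho2, 0, 1)), 0)

    base, water, protein = _spectrum_components(p.shell_color, p.grid, rng)

    crack = None
    for attempt in range(3):
        crack = _crack_mask(p, inside, rng, stretch=1.0 + attempt)
        if p.crack_type == "none" or crack.sum() > 0:
            break
    if p.crack_type != "none" and crack.sum() == 0:
        raise ParameterError("could not place any crack pixels on the shell")

    cube = np.empty((rows, cols, bands), dtype=np.float32)
    cube[:] = p.background_level * (1.0 + 0.1 * rng.standard_normal(bands)
                                    ).astype(np.float32)

    # Per-pixel water-valley depth factor: bound moisture in the membrane
    # varies across the shell, so single-pixel valley depth is an
    # ambiguous crack cue — only the spatial coherence of a crack's
    # deepened valleys is diagnostic.
    dip_j = 1.0 + p.dip_jitter_sd * rng.standard_normal((rows, cols))
    np.clip(dip_j, 0.3, 1.9, out=dip_j)
    # Broadband shell texture (pigment/thickness variability).
    texture = 1.0 + p.texture_sd * rng.standard_normal((rows, cols))
    np.clip(texture, 0.6, 1.4, out=texture)
    gain = (illum * texture).astype(np.float64)

    shell = inside & (crack == 0)
    cube[shell] = (gain[shell, None] * base[None, :]
                   * (1.0 - dip_j[shell, None] * water[None, :]
                      - protein[None, :])).astype(np.float32)
    if crack.sum():
        sel = crack.astype(bool)
        crack_px = (_CRACK_REFLECTANCE_FACTOR * base[None, :]
                    * (1.0 - _CRACK_DIP_DEEPENING * dip_j[sel, None]
                       * water[None, :] - protein[None, :]))
        if p.crack_type == "hairline":
            intact_px = (base[None, :]
                         * (1.0 - dip_j[sel, None] * water[None, :]
                            - protein[None, :]))
            crack_px = (_HAIRLINE_BLEND * crack_px
                        + (1 - _HAIRLINE_BLEND) * intact_px)
        cube[sel] = (gain[sel, None] * crack_px).astype(np.float32)

    # Speckle/stain confounders: broadband intensity blobs on intact
    # shell. Relative valley depths are untouched (spectrally unlike a
    # crack) and the blobs are compact (spatially unlike a crack).
    n_spots = int(rng.poisson(p.spot_density))
    shell_rc = np.argwhere(shell)
    for _ in range(n_spots):
        if not len(shell_rc):
            break
        sr, sc = shell_rc[rng.integers(len(shell_rc))]
        radius = rng.integers(2, 6)
        factor = rng.uniform(0.70, 0.90)
        dist2 = (rr - sr) ** 2 + (cc - sc) ** 2
        spot = (dist2 <= radius ** 2) & shell
        cube[spot] *= np.float32(factor)

    cube += rng.normal(0.0, p.noise_sd, size=cube.shape).astype(np.float32)
    np.clip(cube, 0.0, None, out=cube)

    sc_cube = SpectralCube(
        data=cube, grid=p.grid, kind="reflectance",
        provenance=(f"synthetic egg color={p.shell_color} "
                    f"crack={p.crack_type} severity={p.severity:.2f} "
                    f"seed={p.seed}"),
    )
    return sc_cube, CrackMask(crack)


def sample_scene_params(template: SyntheticSceneParams, index: int,
                        rng: np.random.Generator
                        ) -> tuple[SyntheticSceneParams, dict]:
    """Draw one egg's metadata: color, crack type, impact height/severity."""
    color = SHELL_COLORS[rng.integers(len(SHELL_COLORS))]
    # ~10% of eggs are crack-free controls.
    if rng.random() < 0.10:
        crack_type = "none"
    else:
        crack_type = ("linear", "star", "hairline")[rng.integers(3)]
    height = rng.uniform(0.10, 0.15)
    _, energy = impact_kinematics(ImpactModel(height_m=height))
    severity = severity_from_energy(energy)
    params = replace(template, shell_color=color, crack_type=crack_type,
                     severity=severity,
                     seed=int(rng.integers(0, 2 ** 31 - 1)))
    meta = {"id": f"egg_{index:04d}", "color": color, "crack_type": crack_type,
            "height_m": round(height, 4), "energy_J": round(energy, 4),
            "severity": round(severity, 4)}
    return params, meta


def build_benchmark(n_eggs: int = 100,
                    template: SyntheticSceneParams | None = None,
                    seed: int = 0, out_dir=None):
    """Generate the standard synthetic benchmark.

    Returns ``(scenes, manifest)`` where scenes is a list of
    ``(SpectralCube, CrackMask)`` and manifest a DataFrame of per-egg
    metadata. When ``out_dir`` is given, cubes (ENVI), masks (PNG) and
    ``manifest.csv`` are also written there.
    """
    if n_eggs < 3:
        raise ParameterError("benchmark needs at least 3 eggs")
    template = template or SyntheticSceneParams()
    rng = np.random.default_rng(seed)
    scenes, records = [], []
    for i in range(n_eggs):
        params, meta = sample_scene_params(template, i, rng)
        cube, mask = generate_egg_cube(params)
        meta["crack_pixel_count"] = mask.crack_pixel_count
        scenes.append((cube, mask))
        records.append(meta)
    manifest = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for meta, (cube, mask) in zip(records, scenes):
            write_envi(cube, out_dir / meta["id"], interleave="bil")
            write_mask(mask, out_dir / f"{meta['id']}_mask.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return scenes, manifest


def planted_band_spectra(n_samples: int = 200, n_bands: int = 60,
                         n_informative: int = 5, seed: int = 0
                         ) -> tuple[SpectraMatrix, np.ndarray]:
    """Planted-signal simulation for validating the band selectors.

    The uninformative bands are near-collinear mixtures of three latent
    factors (mimicking redundant neighbouring SWIR bands). The class
    label is the sign of the sum of ``n_informative`` independent
    components, each carried by exactly one planted band — so every
    planted band is individually necessary (synergistic information) and
    no distractor can substitute for it. Returns the matrix and the
    planted band indices.
    """
    rng = np.random.default_rng(seed)
    planted = np.sort(rng.choice(n_bands, size=n_informative, replace=False))

    signal = rng.standard_normal((n_samples, n_informative))
    y = (signal.sum(axis=1) > 0).astype(np.int64)
    if y.min() == y.max():  # vanishing probability at n >= 20; be safe
        y[0] = 1 - y[0]

    latents = rng.standard_normal((n_samples, 3))
    X = np.empty((n_samples, n_bands))
    for j in range(n_bands):
        coeffs = rng.standard_normal(3)
        X[:, j] = latents @ coeffs + 0.3 * rng.standard_normal(n_samples)
    for rank, j in enumerate(planted):
        X[:, j] = signal[:, rank] + 0.1 * rng.standard_normal(n_samples)
    grid = WavelengthGrid(np.linspace(1000.0, 2500.0, n_bands))
    return SpectraMatrix(X=X, y=y, band_grid=grid), planted
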