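"""Spectral preprocessing: black-white calibration, SG smoothing, MSC.

Raw push-broom counts are converted to relative reflectance with the
standard black-white calibration

    I = (I0 - D) / (W - D)

where ``W`` and ``D`` are white- and dark-reference frames. Spectra are
then denoised along the band axis with Savitzky-Golay (SG) polynomial
smoothing and de-scattered with Multiplicative Scatter Correction (MSC),
in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import CrackMask, SpectralCube, WavelengthGrid
from .errors import FormatError, ParameterError
from .io_envi import log

DEFAULT_EPSILON = 1e-6
DEFAULT_CLAMP_MAX = 2.0  # keeps specular outliers bounded
MSC_SLOPE_TOL = 1e-8


@dataclass
class CalibrationFrames:
    """White / dark reference intensities (counts).

    Frames may be full-frame ``(rows, cols, bands)`` or per-column
    ``(cols, bands)`` as produced by a line-scan sensor; per-column frames
    broadcast over rows.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise FormatError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )
        if self.white.ndim not in (2, 3):
            raise FormatError("calibration frames must be 2-D (per-column) or 3-D")


@dataclass
class SpectraMatrix:
    """N labeled pixel spectra: X is N x B reflectance, y in {0, 1}."""

    X: np.ndarray
    y: np.ndarray
    band_grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y).ravel()
        if self.X.ndim != 2:
            raise FormatError("X must be 2-D (samples x bands)")
        if self.X.shape[0] != self.y.size:
            raise FormatError("X rows and y length differ")
        if self.X.shape[0] < 2:
            raise FormatError("need at least 2 spectra")
        if self.X.shape[1] != self.band_grid.count:
            raise FormatError("X band count does not match the wavelength grid")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]


def calibrate(raw: SpectralCube, frames: CalibrationFrames,
              epsilon: float = DEFAULT_EPSILON,
              clamp_max: float = DEFAULT_CLAMP_MAX) -> SpectralCube:
    """Black-white calibrate a raw cube to relative reflectance.

    The denominator ``W - D`` is floored at ``epsilon`` (dead pixels must
    not produce infinities) and the output clamped to ``[0, clamp_max]``.
    Scale-invariant: multiplying I0, W and D by a common positive constant
    leaves the result unchanged.
    """
    if raw.kind != "raw":
        raise ParameterError(f"calibrate expects a raw cube, got kind={raw.kind!r}")
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")

    white, dark = frames.white, frames.dark
    if white.ndim == 2:  # per-column line-sensor frames broadcast over rows
        white = white[np.newaxis, :, :]
        dark = dark[np.newaxis, :, :]
    try:
        np.broadcast_shapes(raw.data.shape, white.shape)
    except ValueError as exc:
        raise FormatError(
            f"calibration frames {frames.white.shape} are not broadcastable "
            f"to cube {raw.data.shape}"
        ) from exc

    denom = white - dark
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        log.warning("calibrate: %d elements with W <= D floored at epsilon", n_bad)
    denom = np.maximum(denom, epsilon)
    refl = (raw.data.astype(np.float64) - dark) / denom
    refl = np.clip(refl, 0.0, clamp_max)
    return SpectralCube(
        data=refl.astype(np.float32),
        grid=raw.grid,
        kind="reflectance",
        provenance=(raw.provenance + " | black-white calibrated").strip(" |"),
    )


def sg_smooth(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smooth spectra along the last (band) axis.

    Reproduces any polynomial of degree <= ``polyorder`` exactly; edges are
    handled by refitting the polynomial on the truncated window
    (``mode='interp'``).
    """
    X = np.asarray(X, dtype=np.float64)
    if window % 2 == 0:
        raise ParameterError("SG window must be odd")
    if window <= polyorder:
        raise ParameterError("SG window must exceed polyorder")
    if window > X.shape[-1]:
        raise ParameterError(
            f"SG window {window} exceeds band count {X.shape[-1]}"
        )
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         axis=-1, mode="interp")


def msc_correct(X: np.ndarray, reference: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative Scatter Correction against a reference spectrum.

    Each spectrum ``x`` is regressed as ``x ≈ a + b * reference`` (OLS) and
    corrected to ``(x - a) / b``, removing additive offset and multiplicative
    scatter. Returns ``(corrected, reference)``; pass the returned reference
    to correct held-out data with the training-set mean (no leakage).
    Rows whose fitted ``|b|`` is below tolerance are left uncorrected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if reference is None:
        if X.shape[0] < 2:
            raise ParameterError("need >= 2 spectra to form a mean reference")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=np.float64).ravel()
    if reference.size != X.shape[1]:
        raise FormatError("reference length does not match band count")

    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise ParameterError("MSC reference is constant; slope undefined")

    x_mean = X.mean(axis=1)
    b = (X - x_mean[:, None]) @ ref_c / denom
    a = x_mean - b * reference.mean()

    corrected = X.copy()
    ok = np.abs(b) >= MSC_SLOPE_TOL
    if not np.all(ok):
        log.warning("msc_correct: %d spectra with near-zero slope skipped",
                    int((~ok).sum()))
    corrected[ok] = (X[ok] - a[ok, None]) / b[ok, None]
    return corrected, reference


def preprocess_cube(cube: SpectralCube, sg_window: int = 11, sg_polyorder: int = 2,
                    msc_reference: np.ndarray | None = None,
                    msc_enabled: bool = True) -> tuple[SpectralCube, np.ndarray | None]:
    """Apply SG smoothing then MSC per pixel across a whole cube.

    Returns the processed cube and the MSC reference used (``None`` when
    MSC is disabled). Negative values introduced by MSC are floored at 0
    to preserve the reflectance contract.
    """
    flat = cube.data.reshape(-1, cube.bands).astype(np.float64)
    flat = sg_smooth(flat, window=sg_window, polyorder=sg_polyorder)
    reference = None
    if msc_enabled:
        flat, reference = msc_correct(flat, reference=msc_reference)
    flat = np.clip(flat, 0.0, None)
    out = SpectralCube(
        data=flat.reshape(cube.shape).astype(np.float32),
        grid=cube.grid,
        kind=cube.kind,
        provenance=(cube.provenance + " | SG+MSC").strip(" |"),
    )
    return out, reference


def extract_labeled_pixels(cube: SpectralCube, mask: CrackMask,
                           n_per_class: int = 200, seed: int = 0) -> SpectraMatrix:
    """Sample up to ``n_per_class`` pixel spectra per class, without replacement.

    Class 1 = crack, class 0 = everything else (shell + background).
    Reproducible under ``seed``.
    """
    if cube.shape[:2] != mask.shape:
        raise FormatError(
            f"cube spatial shape {cube.shape[:2]} != mask shape {mask.shape}"
        )
    rng = np.random.default_rng(seed)
    flat = cube.data.reshape(-1, cube.bands)
    labels = mask.labels.ravel()

    chosen_X, chosen_y = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ParameterError(f"class {cls} has no pixels in the mask")
        take = min(n_per_class, idx.size)
        pick = rng.choice(idx, size=take, replace=False)
        pick.sort()
        chosen_X.append(flat[pick])
        chosen_y.append(np.full(take, cls, dtype=np.int64))

    return SpectraMatrix(
        X=np.vstack(chosen_X),
        y=np.concatenate(chosen_y),
        band_grid=cube.grid,
    )
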