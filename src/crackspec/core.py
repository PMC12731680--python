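"""Core containers for SWIR hyperspectral egg imagery.

A scene is held as a :class:`SpectralCube` — a ``rows x cols x bands``
reflectance (or raw-count) raster with its band axis described by a
:class:`WavelengthGrid` — paired, when annotated, with a binary
:class:`CrackMask` marking crack pixels.

Conventions: row-major, 0-based spatial indices ``(row, col)``; the band
axis is always last in memory regardless of on-disk interleave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

#: Default SWIR band axis: 1000-2500 nm over 273 bands (~5.5 nm sampling).
DEFAULT_N_BANDS = 273
DEFAULT_RANGE_NM = (1000.0, 2500.0)

WAVELENGTH_BOUNDS_NM = (300.0, 3000.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths, in nanometres."""

    centers_nm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.centers_nm, dtype=np.float64).ravel()
        object.__setattr__(self, "centers_nm", arr)
        if arr.size == 0:
            raise FormatError("wavelength grid is empty")
        if np.any(np.diff(arr) <= 0):
            raise FormatError("wavelength centers must be strictly increasing")
        lo, hi = WAVELENGTH_BOUNDS_NM
        if arr[0] < lo or arr[-1] > hi:
            raise FormatError(
                f"wavelengths must lie within [{lo:g}, {hi:g}] nm, "
                f"got [{arr[0]:g}, {arr[-1]:g}]"
            )

    @property
    def count(self) -> int:
        return int(self.centers_nm.size)

    def __len__(self) -> int:
        return self.count

    @classmethod
    def default_swir(cls) -> "WavelengthGrid":
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_BANDS))

    def subset(self, indices) -> "WavelengthGrid":
        idx = np.asarray(indices, dtype=np.intp)
        return WavelengthGrid(self.centers_nm[idx])

    def nearest_index(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers_nm - wavelength_nm)))


@dataclass
class SpectralCube:
    """A rows x cols x bands raster plus its wavelength grid.

    ``kind`` is ``"raw"`` for sensor counts and ``"reflectance"`` for
    black-white-calibrated relative reflectance (unitless, >= 0).
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "reflectance"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"cube must be 3-D, got ndim={self.data.ndim}")
        if self.kind not in ("raw", "reflectance"):
            raise FormatError(f"unknown cube kind {self.kind!r}")
        if self.data.shape[2] != self.grid.count:
            raise FormatError(
                f"band axis ({self.data.shape[2]}) != grid count ({self.grid.count})"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")
        if self.kind == "reflectance" and self.data.min() < 0:
            raise FormatError("reflectance cube contains negative values")

    @property
    def shape(self):
        return self.data.shape

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CrackMask:
    """Binary per-pixel crack labels (1 = crack) aligned with a cube."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise FormatError(f"mask must be 2-D, got ndim={lab.ndim}")
        vals = np.unique(lab)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask values outside {{0,1}}: {vals[:8]}")
        self.labels = lab.astype(np.uint8)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CrackMask":
        """Binarize an arbitrary single-channel raster: positive -> 1."""
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise FormatError("mask source must be single-channel 2-D")
        return cls((arr > 0).astype(np.uint8))

    @property
    def shape(self):
        return self.labels.shape

    @property
    def crack_pixel_count(self) -> int:
        return int(self.labels.sum())
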