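"""ENVI-style hypercube and PNG mask I/O, plus logging setup.

ENVI stores a cube as a plain-text header (``.hdr``) alongside a raw
binary raster. Three interleaves are supported: BSQ (band-sequential),
BIL (band-interleaved-by-line, the push-broom native order) and BIP
(band-interleaved-by-pixel). In memory the band axis is always last;
interleave only affects the byte order on disk.

Masks travel as 8-bit PNG with ``{0, 255}`` on disk and ``{0, 1}`` in
memory; any strictly positive pixel binarizes to 1.
"""

from __future__ import annotations

import logging
import re
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .core import CrackMask, SpectralCube, WavelengthGrid
from .errors import FormatError

log = logging.getLogger("crackspec")

# ENVI numeric "data type" codes supported here.
_DTYPE_BY_CODE = {1: np.uint8, 2: np.int16, 4: np.float32}
_CODE_BY_DTYPE = {np.dtype(v): k for k, v in _DTYPE_BY_CODE.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper()))


def _parse_header(text: str) -> dict:
    """Parse ``key = value`` lines; ``{...}`` values may span lines."""
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    # Collapse brace-delimited blocks onto one line first.
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _brace_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{") and inner.endswith("}"):
        inner = inner[1:-1]
    return [tok.strip() for tok in inner.split(",") if tok.strip()]


def _companion_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for suffix in (".img", ".raw", ".dat", ""):
        candidate = stem.with_suffix(suffix) if suffix else stem
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no companion binary found for {header_path}")


def read_envi(header_path) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    The band axis is reordered to match the header's wavelength list,
    whatever the on-disk interleave.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc

    if dtype_code not in _DTYPE_BY_CODE:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")

    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks a wavelength list")
    wavelengths = [float(w) for w in _brace_list(fields["wavelength"])]
    if len(wavelengths) != bands:
        raise FormatError(
            f"wavelength list length {len(wavelengths)} != bands {bands}"
        )

    binary = _companion_binary(header_path)
    dtype = _DTYPE_BY_CODE[dtype_code]
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(binary, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"binary holds {raw.size} samples, header declares {expected}"
        )

    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    kind = fields.get("cube kind", "reflectance").strip().lower()
    provenance = fields.get("description", "").strip("{} ")
    return SpectralCube(
        data=np.ascontiguousarray(data, dtype=np.float32),
        grid=WavelengthGrid(np.asarray(wavelengths)),
        kind=kind,
        provenance=provenance,
    )


def write_envi(cube: SpectralCube, path, interleave: str = "bil",
               dtype_code: int = 4) -> Path:
    """Write ``cube`` as an ENVI header/binary pair; returns the header path.

    ``path`` may be a base name, the ``.hdr`` path, or the ``.img`` path.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPE_BY_CODE:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")

    base = Path(path)
    if base.suffix in (".hdr", ".img", ".raw", ".dat"):
        base = base.with_suffix("")
    header_path = base.with_suffix(".hdr")
    binary_path = base.with_suffix(".img")
    base.parent.mkdir(parents=True, exist_ok=True)

    rows, cols, bands = cube.shape
    if interleave == "bsq":
        ordered = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = cube.data.transpose(0, 2, 1)
    else:
        ordered = cube.data
    np.ascontiguousarray(ordered, dtype=_DTYPE_BY_CODE[dtype_code]).tofile(binary_path)

    wavelengths = ", ".join(f"{w:.4f}" for w in cube.grid.centers_nm)
    header = (
        "ENVI\n"
        f"description = {{{cube.provenance}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    header_path.write_text(header)
    return header_path


def read_mask(path) -> CrackMask:
    """Read a single-channel raster and binarize it (positive -> 1)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        # A paletted/replicated grayscale PNG is fine if channels agree.
        if arr.shape[2] in (3, 4) and np.all(arr[..., :3] == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise FormatError("mask image must be single-channel")
    if arr.ndim != 2:
        raise FormatError(f"mask image must be 2-D, got ndim={arr.ndim}")
    return CrackMask.from_array(arr)


def write_mask(mask: CrackMask, path) -> Path:
    """Write a mask as an 8-bit PNG with values {0, 255}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.labels * np.uint8(255)))
    return path


def load_yaml_config(path) -> dict:
    """Load a YAML mapping; empty files load as an empty dict."""
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise FormatError("configuration file must contain a YAML mapping")
    return loaded
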