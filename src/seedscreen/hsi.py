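"""Hyperspectral cube I/O, reflectance calibration and band trimming.

Cubes are stored as ``(row, column, band)`` float arrays with a strictly
increasing wavelength axis in nanometres.  A minimal ENVI dialect
(plain-text ``.hdr`` plus a raw binary data file) is supported for both
reading and writing; the writer exists mainly to produce test fixtures
and small interchange files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "CalibrationRefs",
    "FormatError",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "trim_bands",
    "export_wavelengths",
]


class FormatError(ValueError):
    """Raised when an on-disk cube is malformed or self-contradictory."""


# ENVI "data type" codes -> numpy dtypes (subset we read/write)
_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


@dataclass
class Hypercube:
    """A calibrated (or raw) spectral image cube.

    Attributes
    ----------
    data:
        3-D array indexed ``(row, column, band)``.
    wavelengths:
        Band-centre wavelengths in nm, strictly increasing, one per band.
    meta:
        Free-form acquisition / processing annotations.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (row, col, band), got ndim={self.data.ndim}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.shape} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("wavelengths must be finite")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class CalibrationRefs:
    """White / dark reference frames sharing the cube's band axis.

    ``white`` and ``dark`` may be full frames ``(row, col, band)`` or
    per-band vectors ``(band,)``; anything broadcastable to the cube works.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


def calibrate_reflectance(raw: Hypercube, refs: CalibrationRefs) -> Hypercube:
    """Flat-field calibration ``R = (I - D) / (W - D)``.

    Pixels/bands where ``white == dark`` are set to NaN and counted in
    ``meta['n_invalid']``.  Reflectance is deliberately *not* clipped to
    ``[0, 1]``: glossy seed coats can locally exceed the white reference;
    the count of such pixels is recorded in ``meta['n_above_one']``.
    """
    if refs.white.shape[-1] != raw.n_bands or refs.dark.shape[-1] != raw.n_bands:
        raise ValueError(
            f"reference band axis ({refs.white.shape[-1]}) does not match cube "
            f"band count ({raw.n_bands})"
        )
    denom = refs.white - refs.dark
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - refs.dark) / denom
    invalid = np.broadcast_to(denom == 0, refl.shape)
    refl = np.where(invalid, np.nan, refl)
    meta = dict(raw.meta)
    meta["calibrated"] = True
    meta["n_invalid"] = int(invalid.sum())
    meta["n_above_one"] = int(np.nansum(refl > 1.0))
    return Hypercube(refl, raw.wavelengths.copy(), meta)


def trim_bands(cube: Hypercube, low_nm: float = 400.0, high_nm: float = 1000.0) -> Hypercube:
    """Retain exactly the bands with ``low_nm <= lambda <= high_nm`` (closed interval).

    Band order is preserved.  Raises ``ValueError`` if no band survives.
    """
    keep = (cube.wavelengths >= low_nm) & (cube.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(
            f"trim range [{low_nm}, {high_nm}] nm retains no band of the cube "
            f"({cube.wavelengths[0]:.1f}-{cube.wavelengths[-1]:.1f} nm)"
        )
    meta = dict(cube.meta)
    meta["trim_nm"] = (float(low_nm), float(high_nm))
    return Hypercube(cube.data[:, :, keep], cube.wavelengths[keep], meta)


# ---------------------------------------------------------------------------
# ENVI dialect
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict (keys lower-cased)."""
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    # join { ... } groups onto one line
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    header: dict = {}
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip().lower()] = value.strip()
    return header


def _parse_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", ",").split(",") if tok.strip()]


def _resolve_pair(path: Path) -> tuple[Path, Path]:
    """Resolve a user-supplied path into (header, data) files."""
    path = Path(path)
    if path.suffix == ".hdr":
        hdr = path
        base = path.with_suffix("")
    else:
        base = path
        hdr = path.with_suffix(path.suffix + ".hdr") if path.suffix else Path(str(path) + ".hdr")
        if not hdr.exists():
            hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"ENVI header not found for {path}")
    for cand in (base, base.with_suffix(".img"), base.with_suffix(".dat")):
        if cand.exists() and cand.is_file() and cand != hdr:
            return hdr, cand
    raise FormatError(f"ENVI data file not found for {path}")


def read_cube(path, dialect: str = "envi") -> Hypercube:
    """Read a hypercube from an ENVI header/data pair.

    ``path`` may point at the header, the data file, or their common stem.
    Wavelengths are converted to nm when the header declares micrometre
    units.
    """
    if dialect != "envi":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    hdr_path, data_path = _resolve_pair(Path(path))
    header = _parse_envi_header(hdr_path.read_text())

    try:
        samples = int(header["samples"])
        lines = int(header["lines"])
        bands = int(header["bands"])
        dtype_code = int(header["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in header:
        raise FormatError("ENVI header declares no wavelength list")
    wavelengths = np.array(_parse_list(header["wavelength"]), dtype=float)
    if len(wavelengths) != bands:
        raise FormatError(
            f"header declares {len(wavelengths)} wavelengths but {bands} bands"
        )
    units = header.get("wavelength units", "nm").lower()
    if units.startswith(("micro", "um", "µm")):
        wavelengths = wavelengths * 1000.0

    interleave = header.get("interleave", "bsq").lower()
    offset = int(header.get("header offset", 0))
    byte_order = int(header.get("byte order", 0))
    dtype = np.dtype(_DTYPE_CODES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")

    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"data file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")

    meta = {"source": str(data_path), "interleave": interleave}
    for key in ("description", "acquisition time"):
        if key in header:
            meta[key] = header[key]
    return Hypercube(np.ascontiguousarray(data, dtype=float), wavelengths, meta)


def write_cube(cube: Hypercube, path, interleave: str = "bip") -> tuple[Path, Path]:
    """Write ``cube`` as an ENVI pair ``<path>.img`` + ``<path>.hdr``.

    Data are stored float64 little-endian so a read round-trip is
    bit-exact.  Returns ``(header_path, data_path)``.
    """
    base = Path(path)
    if base.suffix in {".hdr", ".img", ".dat"}:
        base = base.with_suffix("")
    hdr_path = base.with_suffix(".hdr")
    data_path = base.with_suffix(".img")

    rows, cols, bands = cube.data.shape
    arr = np.asarray(cube.data, dtype="<f8")
    if interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        out = arr
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    out.tofile(data_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr_path, data_path


def export_wavelengths(cube: Hypercube, path) -> None:
    """Write the wavelength axis as a one-column CSV."""
    with open(path, "w") as fh:
        fh.write("wavelength_nm\n")
        for w in cube.wavelengths:
            fh.write(f"{w:.6f}\n")
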