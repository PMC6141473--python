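"""Minimal ENVI band-sequential raster I/O.

Cubes are stored as a flat binary file (``.img``) plus an ENVI text header
(``.hdr``) carrying the standard fields: samples, lines, bands, data type,
interleave and, for spectral cubes, the wavelength list.  Only the subset of
the format this package writes is supported on read: BSQ interleave, byte
order 0, header offset 0.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

# ENVI data-type codes <-> numpy dtypes (little-endian, byte order 0)
_DTYPE_TO_CODE = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}


def _header_path(path: str) -> str:
    base, ext = os.path.splitext(path)
    if ext.lower() == ".hdr":
        return path
    return path + ".hdr"


def write_envi(
    path: str,
    array: np.ndarray,
    wavelengths: Sequence[float] | None = None,
    description: str = "",
) -> None:
    """Write a 2D (lines, samples) or 3D (lines, samples, bands) array.

    3D arrays are written band-sequential.  ``path`` is the data file; the
    header is written next to it as ``path + '.hdr'``.
    """
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D array, got ndim={arr.ndim}")
    if arr.dtype not in _DTYPE_TO_CODE:
        arr = arr.astype(np.float32)
    lines, samples, bands = arr.shape
    if wavelengths is not None and len(wavelengths) != bands:
        raise ValueError("wavelength count does not match band count")

    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(arr, 2, 0)).tofile(path)

    fields = [
        "ENVI",
        f"description = {{{description}}}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_CODE[arr.dtype]}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in wavelengths)
        fields.append("wavelength units = Nanometers")
        fields.append(f"wavelength = {{{wl}}}")
    with open(_header_path(path), "w") as fh:
        fh.write("\n".join(fields) + "\n")


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a dict of lower-cased keys."""
    out: dict = {}
    # join brace-delimited values that span lines
    buf = ""
    in_braces = False
    lines = []
    for raw in text.splitlines():
        if in_braces:
            buf += " " + raw.strip()
            if "}" in raw:
                lines.append(buf)
                in_braces = False
            continue
        if "{" in raw and "}" not in raw:
            buf = raw.strip()
            in_braces = True
        else:
            lines.append(raw.strip())
    for line in lines:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and val.endswith("}"):
            val = val[1:-1].strip()
        out[key] = val
    return out


def read_envi(path: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a BSQ ENVI raster; return ``(array, wavelengths)``.

    The array comes back as (lines, samples, bands); single-band rasters are
    squeezed to (lines, samples).  ``wavelengths`` is None when the header
    has no wavelength list.
    """
    with open(_header_path(path)) as fh:
        hdr = _parse_header(fh.read())
    samples = int(hdr["samples"])
    lines = int(hdr["lines"])
    bands = int(hdr["bands"])
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError(f"unsupported interleave {hdr.get('interleave')!r}")
    dtype = _CODE_TO_DTYPE[int(hdr["data type"])]
    data = np.fromfile(path, dtype=dtype, count=bands * lines * samples)
    if data.size != bands * lines * samples:
        raise ValueError(f"file {path} shorter than header promises")
    cube = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    wavelengths = None
    if "wavelength" in hdr:
        wavelengths = np.array(
            [float(tok) for tok in hdr["wavelength"].split(",") if tok.strip()]
        )
    if cube.shape[2] == 1:
        return cube[:, :, 0], wavelengths
    return cube, wavelengths
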