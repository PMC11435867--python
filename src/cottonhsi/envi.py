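"""Minimal ENVI raster I/O (text ``.hdr`` + raw binary), BSQ/BIL/BIP.

Supports the data types common on laboratory hyperspectral cameras:
8-bit unsigned (1), 16-bit unsigned (12), 32-bit float (4) and
64-bit float (5). Other codes are rejected rather than guessed at.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .cube import HsiCube

__all__ = ["read_envi", "write_envi", "EnviFormatError", "EnviCorruptionError"]

# ENVI data-type code <-> numpy dtype
_DTYPES = {1: np.uint8, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


class EnviFormatError(ValueError):
    """Header is missing required fields or declares unsupported values."""


class EnviCorruptionError(ValueError):
    """Binary payload size disagrees with the header."""


def _header_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path
    return path + ".hdr"


def _data_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path[: -len(".hdr")]
    return path


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    # key = value, where a value may be a { ... } block spanning lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)\s*$", re.S | re.M)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def _parse_list(raw: str) -> list:
    inner = raw.strip().lstrip("{").rstrip("}")
    return [item.strip() for item in inner.split(",") if item.strip()]


def read_envi(path: str) -> HsiCube:
    """Read an ENVI raster into an :class:`HsiCube` with (row, col, band) order.

    ``path`` may point at the binary file or at its ``.hdr`` companion.
    """
    hdr = _header_path(path)
    dat = _data_path(path)
    if not os.path.exists(hdr):
        raise FileNotFoundError(hdr)
    with open(hdr, "r") as fh:
        fields = _parse_header(fh.read())

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise EnviFormatError(f"header missing required field '{required}'")

    samples = int(fields["samples"])  # cols
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    offset = int(fields.get("header offset", 0))
    byte_order = int(fields.get("byte order", 0))

    if code not in _DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave '{interleave}'")

    dtype = np.dtype(_DTYPES[code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")

    expected = samples * lines * bands
    raw = np.fromfile(dat, dtype=dtype, offset=offset)
    if raw.size != expected:
        raise EnviCorruptionError(
            f"binary holds {raw.size} samples but header declares {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )

    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    data = np.ascontiguousarray(data)
    if byte_order == 1:
        data = data.astype(data.dtype.newbyteorder("="))

    if "wavelength" in fields:
        wavelengths = np.array([float(w) for w in _parse_list(fields["wavelength"])])
    else:
        wavelengths = np.arange(bands, dtype=float)

    meta = {
        k: v
        for k, v in fields.items()
        if k not in ("samples", "lines", "bands", "data type", "interleave", "wavelength", "header offset", "byte order")
    }
    return HsiCube(data=data, wavelengths=wavelengths, meta=meta)


def write_envi(cube: HsiCube, path: str, interleave: str = "bsq") -> None:
    """Write ``cube`` as an ENVI raster (binary at ``path``, header at ``path + '.hdr'``).

    Round-trips bit-exactly through :func:`read_envi` for the supported dtypes.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    data = np.asarray(cube.data)
    if data.ndim != 3 or data.shape[2] < 1:
        raise ValueError("cube must be 3-D with at least one band")
    dtype = np.dtype(data.dtype)
    if dtype not in _CODES:
        raise EnviFormatError(f"unsupported dtype {dtype}; use one of {sorted(str(d) for d in _CODES)}")

    rows, cols, bands = data.shape
    if interleave == "bsq":
        payload = data.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = data.transpose(0, 2, 1)
    else:
        payload = data

    dat = _data_path(path)
    np.ascontiguousarray(payload).tofile(dat)

    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths) + "}",
    ]
    for key, val in cube.meta.items():
        lines.append(f"{key} = {val}")
    with open(_header_path(dat), "w") as fh:
        fh.write("\n".join(lines) + "\n")
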