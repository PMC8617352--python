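"""Minimal ENVI raster I/O (band-sequential, text header + raw binary).

Supports the subset of the ENVI format the pipeline needs: BSQ interleave,
little-endian, float32/float64/uint16/int32 payloads, and a ``wavelength``
header list.  The header is a plain-text ``key = value`` file where list
values are wrapped in braces; the payload is a headerless binary file.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .exceptions import FormatError

# ENVI "data type" codes <-> numpy dtypes (little-endian)
_DTYPES = {2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_envi(path, data: np.ndarray, wavelengths=None, meta: dict | None = None):
    """Write a (lines, samples, bands) array as ``path``.raw + ``path``.hdr.

    ``wavelengths`` (nm, length = bands) is stored in the header; extra
    scalar metadata may be passed via ``meta``.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:  # single-band raster (e.g. a label mask)
        data = data[:, :, None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2-D or 3-D array, got shape {data.shape}")
    lines, samples, bands = data.shape
    dtype = np.dtype(data.dtype)
    if dtype not in _CODES:
        raise FormatError(f"unsupported dtype {dtype} for ENVI output")
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.shape != (bands,):
            raise FormatError(
                f"wavelength length {wavelengths.size} != bands {bands}"
            )

    raw = path.with_suffix(".raw")
    hdr = path.with_suffix(".hdr")
    # BSQ: band-sequential on disk
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(raw)

    lines_out = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[dtype]}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in wavelengths)
        lines_out.append("wavelength units = Nanometers")
        lines_out.append(f"wavelength = {{ {wl} }}")
    for key, value in (meta or {}).items():
        lines_out.append(f"{key} = {value}")
    hdr.write_text("\n".join(lines_out) + "\n")


def _parse_header(text: str) -> dict:
    # collapse brace-lists onto one logical line, then parse key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path, *, require_wavelength: bool = True):
    """Read ``path``(.hdr/.raw) back as ``(data, wavelengths, meta)``.

    ``data`` has shape (lines, samples, bands).  ``wavelengths`` is ``None``
    when the header carries no wavelength field and ``require_wavelength``
    is False.

    Raises
    ------
    FormatError
        On missing/inconsistent header fields or a payload whose size does
        not match the declared dimensions.
    """
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    if not hdr.exists():
        raise FormatError(f"missing header file {hdr}")
    if not raw.exists():
        raise FormatError(f"missing payload file {raw}")
    fields = _parse_header(hdr.read_text())

    def _int_field(name: str) -> int:
        if name not in fields:
            raise FormatError(f"header missing required field {name!r}")
        try:
            return int(fields[name])
        except ValueError as exc:
            raise FormatError(f"header field {name!r} is not an integer") from exc

    samples = _int_field("samples")
    lines = _int_field("lines")
    bands = _int_field("bands")
    code = _int_field("data type")
    if code not in _DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"only BSQ interleave supported, got {interleave!r}")
    if fields.get("byte order", "0").strip() != "0":
        raise FormatError("only little-endian (byte order = 0) supported")

    dtype = np.dtype(_DTYPES[code])
    expected = lines * samples * bands * dtype.itemsize
    actual = raw.stat().st_size
    if expected != actual:
        raise FormatError(
            f"payload size {actual} B does not match header "
            f"{lines}x{samples}x{bands} {dtype.name} ({expected} B)"
        )
    flat = np.fromfile(raw, dtype=dtype)
    data = np.moveaxis(flat.reshape(bands, lines, samples), 0, 2)

    wavelengths = None
    if "wavelength" in fields:
        body = fields["wavelength"].strip()
        if not (body.startswith("{") and body.endswith("}")):
            raise FormatError("malformed wavelength list in header")
        values = [v for v in re.split(r"[,\s]+", body[1:-1].strip()) if v]
        if len(values) != bands:
            raise FormatError(
                f"wavelength list length {len(values)} != bands {bands}"
            )
        wavelengths = np.array([float(v) for v in values])
    elif require_wavelength:
        raise FormatError("header missing required field 'wavelength'")

    meta = {
        k: v
        for k, v in fields.items()
        if k
        not in {
            "samples",
            "lines",
            "bands",
            "data type",
            "interleave",
            "byte order",
            "wavelength",
            "wavelength units",
            "header offset",
            "file type",
        }
    }
    return data, wavelengths, meta
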