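"""Minimal ENVI header+raw and .npz archive I/O for hypercubes.

Writes band-sequential (BSQ) float32 raw data next to a plain-text ``.hdr``
file carrying the spatial/spectral dimensions and the wavelength list; the
``.npz`` archive form stores the same arrays portably (data, wavelengths,
white/dark references) and needs no sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .hsi import HyperCube

__all__ = ["write_envi", "read_envi", "save_cube_npz", "load_cube_npz"]

_DTYPE = np.float32  # ENVI data type 4


def write_envi(cube: HyperCube, base_path) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` + ``<base>.raw`` (BSQ, float32, little-endian)."""
    base = Path(base_path)
    hdr_path = base.with_suffix(".hdr")
    raw_path = base.with_suffix(".raw")
    rows, cols, bands = cube.data.shape
    wl = ", ".join(f"{w:.3f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {extractopt hypercube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header, encoding="utf-8")
    # BSQ: band-major layout.
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype=_DTYPE).tofile(raw_path)
    return hdr_path, raw_path


def _parse_header(text: str) -> dict:
    # Collapse brace-delimited multi-line values before splitting on '='.
    fields = {}
    buffer = ""
    for line in text.splitlines():
        buffer += line.strip() + " "
        if buffer.count("{") == buffer.count("}"):
            if "=" in buffer:
                key, _, value = buffer.partition("=")
                fields[key.strip().lower()] = value.strip()
            buffer = ""
    return fields


def read_envi(base_path) -> HyperCube:
    """Read a cube written by :func:`write_envi` (BSQ float32 subset of ENVI)."""
    base = Path(base_path)
    hdr_path = base.with_suffix(".hdr")
    raw_path = base.with_suffix(".raw")
    fields = _parse_header(hdr_path.read_text(encoding="utf-8"))
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValidationError(f"ENVI header missing field {exc}") from exc
    if fields.get("data type", "4") != "4":
        raise ValidationError("only data type 4 (float32) is supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValidationError("only BSQ interleave is supported")
    wl_text = fields.get("wavelength", "").strip().strip("{}")
    wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
    if len(wavelengths) != bands:
        raise ValidationError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )
    raw = np.fromfile(raw_path, dtype=_DTYPE)
    if raw.size != rows * cols * bands:
        raise ValidationError(
            f"raw file holds {raw.size} values, expected {rows * cols * bands}"
        )
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(float)
    return HyperCube(data=data, wavelengths=wavelengths)


def save_cube_npz(cube: HyperCube, path) -> Path:
    """Portable array-archive form (no sidecar header needed)."""
    path = Path(path)
    arrays = {
        "data": cube.data,
        "wavelengths": cube.wavelengths,
        "corrected": np.array(cube.corrected),
    }
    if cube.white_ref is not None:
        arrays["white_ref"] = cube.white_ref
    if cube.dark_ref is not None:
        arrays["dark_ref"] = cube.dark_ref
    np.savez_compressed(path, **arrays)
    return path


def load_cube_npz(path) -> HyperCube:
    with np.load(path) as npz:
        return HyperCube(
            data=npz["data"],
            wavelengths=npz["wavelengths"],
            white_ref=npz["white_ref"] if "white_ref" in npz else None,
            dark_ref=npz["dark_ref"] if "dark_ref" in npz else None,
            corrected=bool(npz["corrected"]),
        )
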