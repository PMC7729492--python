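"""Reading and writing hyperspectral maps and compartment masks.

Two self-describing formats are supported:

``envi_style``
    An ENVI-like pair of files: a text header (``.hdr``) with ``samples``,
    ``lines``, ``bands``, ``data type``, ``interleave = bsq``, the wavenumber
    list and the pixel size, next to a band-sequential little-endian binary
    cube. Rasters are stored as 32-bit floats.

``matrix_table``
    A plain whitespace-delimited table: a ``# pixel_um`` comment, a header
    line ``row col <w1> <w2> ...`` carrying the axis, then one line per pixel
    with its grid indices and absorbances (>= 6 significant digits).

Wavenumber axes may be stored descending in files; maps are always returned
with ascending axes and the original order noted in the metadata.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import FormatError
from .hypermap import CompartmentMask, HyperMap, SpectralAxis

FORMATS = ("envi_style", "matrix_table")

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 1: np.uint8, 2: np.int16, 3: np.int32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# ENVI-style header + BSQ cube
# ---------------------------------------------------------------------------

def _hdr_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def _parse_envi_header(text: str) -> dict:
    """Parse ``key = value`` lines; ``{...}`` blocks may span lines."""
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().startswith("ENVI"):
        body = body.lstrip()[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:]
        if rest.lstrip().startswith("{"):
            open_at = rest.find("{")
            close_at = rest.find("}", open_at)
            if close_at < 0:
                raise FormatError(f"unterminated '{{' block for header key {key!r}")
            fields[key] = rest[open_at + 1:close_at]
            pos = eq + 1 + close_at + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            fields[key] = rest[:nl].strip()
            pos = eq + 1 + nl + 1
    return fields


def _write_envi(path: Path, cube: np.ndarray, wavenumbers: np.ndarray,
                pixel_um: float, dtype: np.dtype) -> None:
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.6g}" for w in wavenumbers)
    header = (
        "ENVI\n"
        "description = {ftiri hyperspectral map}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"pixel_um = {pixel_um:.6g}\n"
        "wavelength units = cm-1\n"
        "wavelength = {" + wl + "}\n"
    )
    _hdr_path(path).write_text(header)
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(cube, 2, 0)).astype(dtype).tofile(path)


def _read_envi(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    hdr = _hdr_path(path)
    if not hdr.exists():
        raise FormatError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        pixel_um = float(fields["pixel_um"])
    except KeyError as exc:
        raise FormatError(f"ENVI header {hdr} lacks required key {exc}") from exc
    if fields.get("interleave", "bsq").strip().lower() != "bsq":
        raise FormatError("only bsq interleave is supported")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    wl_text = fields.get("wavelength", "").replace(",", " ").split()
    wavenumbers = np.array([float(w) for w in wl_text])
    if wavenumbers.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavenumbers.size} wavenumbers"
        )
    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
    expected = rows * cols * bands
    if raw.size != expected:
        raise FormatError(
            f"cube file holds {raw.size} values but header declares {expected} "
            f"({rows}x{cols}x{bands})"
        )
    cube = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(float)
    return cube, wavenumbers, pixel_um


# ---------------------------------------------------------------------------
# matrix_table: one row per pixel
# ---------------------------------------------------------------------------

def _write_table(path: Path, cube: np.ndarray, wavenumbers: np.ndarray,
                 pixel_um: float, integer: bool = False) -> None:
    rows, cols, bands = cube.shape
    with open(path, "w") as fh:
        fh.write(f"# pixel_um = {pixel_um:.6g}\n")
        fh.write("row col " + " ".join(f"{w:.6g}" for w in wavenumbers) + "\n")
        fmt = "%d" if integer else "%.8g"
        for r in range(rows):
            for c in range(cols):
                vals = " ".join(fmt % v for v in cube[r, c])
                fh.write(f"{r} {c} {vals}\n")


def _read_table(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    pixel_um = None
    header = None
    data_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "pixel_um" in line and "=" in line:
                    pixel_um = float(line.split("=", 1)[1])
                continue
            if header is None:
                header = line.split()
                continue
            data_rows.append(line.split())
    if header is None or not data_rows:
        raise FormatError(f"{path} holds no spectra")
    if pixel_um is None:
        raise FormatError(f"{path} lacks a '# pixel_um = ...' line")
    if header[:2] != ["row", "col"]:
        raise FormatError("matrix table header must start with 'row col'")
    wavenumbers = np.array([float(w) for w in header[2:]])
    n_w = wavenumbers.size
    table = np.empty((len(data_rows), n_w + 2))
    for i, parts in enumerate(data_rows):
        if len(parts) != n_w + 2:
            raise FormatError(
                f"row {i} holds {len(parts) - 2} absorbances but the axis "
                f"declares {n_w} points"
            )
        table[i] = [float(p) for p in parts]
    rr = table[:, 0].astype(int)
    cc = table[:, 1].astype(int)
    rows, cols = rr.max() + 1, cc.max() + 1
    if rr.min() < 0 or cc.min() < 0 or len(data_rows) != rows * cols:
        raise FormatError("matrix table does not cover a dense pixel grid")
    cube = np.empty((rows, cols, n_w))
    cube[rr, cc] = table[:, 2:]
    return cube, wavenumbers, pixel_um


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def write_map(hmap: HyperMap, path: str | os.PathLike, format: str = "envi_style") -> None:
    """Write a map so that :func:`read_map` inverts it."""
    _check_format(format)
    path = Path(path)
    if format == "envi_style":
        _write_envi(path, hmap.cube, hmap.axis.wavenumbers, hmap.pixel_um,
                    np.dtype(np.float32))
    else:
        _write_table(path, hmap.cube, hmap.axis.wavenumbers, hmap.pixel_um)


def read_map(path: str | os.PathLike, format: str = "envi_style") -> HyperMap:
    """Read a map, normalizing the axis to ascending wavenumber order."""
    _check_format(format)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "envi_style":
        cube, wavenumbers, pixel_um = _read_envi(path)
    else:
        cube, wavenumbers, pixel_um = _read_table(path)
    order = "ascending"
    if wavenumbers.size >= 2 and wavenumbers[0] > wavenumbers[-1]:
        wavenumbers = wavenumbers[::-1].copy()
        cube = cube[:, :, ::-1].copy()
        order = "descending"
    axis = SpectralAxis(wavenumbers)  # rejects non-monotonic axes
    return HyperMap(
        axis=axis, cube=cube, pixel_um=pixel_um,
        metadata={"source": str(path), "source_axis_order": order},
    )


def write_mask(mask: CompartmentMask, path: str | os.PathLike,
               format: str = "envi_style") -> None:
    """Write a label mask as a single-band raster in the chosen format."""
    _check_format(format)
    path = Path(path)
    cube = mask.labels[:, :, None].astype(np.int16)
    # label rasters carry a single placeholder "band" at 0 cm^-1 equivalent;
    # use a sentinel wavenumber list of one entry
    if format == "envi_style":
        _write_envi(path, cube, np.array([1000.0]), mask.pixel_um,
                    np.dtype(np.int16))
    else:
        _write_table(path, cube, np.array([1000.0]), mask.pixel_um, integer=True)


def read_mask(path: str | os.PathLike, format: str = "envi_style") -> CompartmentMask:
    _check_format(format)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "envi_style":
        cube, _, pixel_um = _read_envi(path)
    else:
        cube, _, pixel_um = _read_table(path)
    if cube.shape[2] != 1:
        raise FormatError("a mask raster must hold exactly one band")
    return CompartmentMask(labels=np.rint(cube[:, :, 0]).astype(np.int64),
                           pixel_um=pixel_um)
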