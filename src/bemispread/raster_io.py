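"""Esri ASCII grid reader/writer.

The simulator exchanges all of its gridded layers (land cover, altitude,
carrying capacity, friction, density snapshots, arrival times) as plain-text
Esri ASCII grids.  The dialect accepted here is deliberately liberal: header
keys are case-insensitive, ``xllcenter``/``yllcenter`` origins are converted
to the corner convention, and unknown header lines before the data block are
ignored (GIS exports are routinely hand-edited).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_NODATA = -9999.0

#: header keys that locate the grid origin at the centre of the lower-left
#: cell instead of its corner
_CENTER_KEYS = {"xllcenter", "yllcenter"}
_HEADER_KEYS = {
    "ncols",
    "nrows",
    "xllcorner",
    "yllcorner",
    "xllcenter",
    "yllcenter",
    "cellsize",
    "nodata_value",
}


class RasterFormatError(ValueError):
    """Raised when an ASCII grid stream violates the format contract."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and NODATA sentinel of a north-up raster grid."""

    ncols: int
    nrows: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=tol)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=tol)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=tol, abs_tol=tol)
        )


@dataclass
class RasterLayer:
    """A north-up numeric grid: row 0 is the northernmost row.

    ``values`` is an ``(nrows, ncols)`` float array; ``mask`` is True on
    NODATA cells, whose ``values`` entries carry no meaning.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.spec, self.values.copy(), self.mask.copy())

    def filled(self) -> np.ndarray:
        """Values with NODATA cells replaced by the sentinel."""
        out = self.values.copy()
        out[self.mask] = self.spec.nodata_value
        return out

    def equals(self, other: "RasterLayer", tol: float = 1e-9) -> bool:
        if not self.spec.approx_equal(other.spec, tol):
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        a, b = self.values[~self.mask], other.values[~other.mask]
        return bool(np.allclose(a, b, rtol=0.0, atol=tol))


def _parse_number(token: str, key: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise RasterFormatError(f"header key {key!r} has non-numeric value {token!r}") from exc


def read_ascii_grid(source) -> RasterLayer:
    """Parse an Esri ASCII grid from a path, string or open text stream.

    Header keys are matched case-insensitively; unrecognised header lines
    (a word followed by anything) before the data block are skipped.
    ``*llcenter`` origins are shifted by half a cell to the corner
    convention.  NODATA defaults to -9999 when the header omits it.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip()[:1].isdigit():
            # looks like a path, not inline content
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()

    header: dict[str, float] = {}
    data_tokens: list[str] = []
    center_x = center_y = False
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        key = parts[0].lower()
        if key in _HEADER_KEYS:
            if len(parts) != 2:
                raise RasterFormatError(f"malformed header line for key {key!r}: {line!r}")
            canonical = key
            if key == "xllcenter":
                canonical, center_x = "xllcorner", True
            elif key == "yllcenter":
                canonical, center_y = "yllcorner", True
            header[canonical] = _parse_number(parts[1], key)
        elif _is_numeric(parts[0]):
            break  # start of the data block
        else:
            continue  # tolerated unknown header line (hand-edited exports)
    else:
        i += 1  # no data block at all; fall through to count check

    for line in lines[i:]:
        data_tokens.extend(line.split())

    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise RasterFormatError(f"missing required header key {required!r}")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    xll = header["xllcorner"] - (cellsize / 2.0 if center_x else 0.0)
    yll = header["yllcorner"] - (cellsize / 2.0 if center_y else 0.0)

    expected = nrows * ncols
    if len(data_tokens) != expected:
        raise RasterFormatError(
            f"expected {expected} data values ({nrows}x{ncols}), got {len(data_tokens)}"
        )
    try:
        values = np.array([float(t) for t in data_tokens], dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise RasterFormatError(f"non-numeric token in data block: {exc}") from exc

    spec = GridSpec(ncols, nrows, xll, yll, cellsize, nodata)
    mask = values == nodata
    return RasterLayer(spec, values, mask)


def _is_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_ascii_grid(layer: RasterLayer, dest=None) -> str:
    """Serialize a layer to Esri ASCII; returns the text (and writes *dest*).

    Masked cells are emitted as the NODATA sentinel.  A non-finite value on
    an unmasked cell is a contract violation.
    """
    unmasked = layer.values[~layer.mask]
    if unmasked.size and not np.all(np.isfinite(unmasked)):
        raise ValueError("cannot serialize non-finite unmasked values")
    spec = layer.spec
    buf = io.StringIO()
    buf.write(f"ncols {spec.ncols}\n")
    buf.write(f"nrows {spec.nrows}\n")
    buf.write(f"xllcorner {_fmt(spec.xllcorner)}\n")
    buf.write(f"yllcorner {_fmt(spec.yllcorner)}\n")
    buf.write(f"cellsize {_fmt(spec.cellsize)}\n")
    buf.write(f"NODATA_value {_fmt(spec.nodata_value)}\n")
    filled = layer.filled()
    for row in filled:
        buf.write(" ".join(_fmt(v) for v in row))
        buf.write("\n")
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def _fmt(v: float) -> str:
    """Compact numeric formatting: integers without a decimal point."""
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))
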