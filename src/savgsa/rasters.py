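"""Minimal ESRI ASCII grid (.asc) reader/writer.

The format is a six-line text header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by whitespace-separated rows, top row
first.  Sufficient for exchanging the mean/SD HSI maps with any GIS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_ascii_grid", "read_ascii_grid"]

NODATA = -9999.0


def write_ascii_grid(
    path,
    data: np.ndarray,
    cellsize: float,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = NODATA,
    fmt: str = "%.8g",
) -> None:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("raster data must be 2-D")
    nrows, ncols = data.shape
    out = np.where(np.isfinite(data), data, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xllcorner:.8g}\n"
        f"yllcorner {yllcorner:.8g}\n"
        f"cellsize {cellsize:.8g}\n"
        f"NODATA_value {nodata:.8g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Return ``(data, header)`` with NODATA cells as NaN."""
    lines = Path(path).read_text().splitlines()
    header: dict = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    data = np.loadtxt(lines[i:]).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header
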