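"""File I/O: ESRI ASCII grids, daily forcing CSV, atomic writes,
run manifests.

Grid rasters use the plain-text ESRI ASCII format (row 0 = north,
origin at the lower-left corner, square cells).  All writers go
through a temp-file + rename so outputs are never half-written.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridDomain

__all__ = [
    "read_raster",
    "write_raster",
    "read_forcing",
    "write_forcing",
    "atomic_write_text",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed raster file."""


class ValidationError(ValueError):
    """Inconsistent forcing data."""


def atomic_write_text(path, text: str) -> None:
    """Write text atomically (temp file + rename in the same dir)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_raster(path, values: np.ndarray, domain: GridDomain,
                 nodata: float = -9999.0, fmt: str = "%.10g") -> None:
    """Write a grid as an ESRI ASCII raster (lossless round trip at
    the stated precision)."""
    values = np.asarray(values)
    if values.shape != domain.shape:
        raise FormatError("values do not match the domain shape")
    vals = np.where(np.isfinite(values), values, nodata)
    lines = [
        f"ncols {domain.n_cols}",
        f"nrows {domain.n_rows}",
        "xllcorner 0.0",
        "yllcorner 0.0",
        f"cellsize {domain.cell_size:.10g}",
        f"NODATA_value {nodata:.10g}",
    ]
    for row in vals:
        lines.append(" ".join(fmt % v for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_raster(path, expected: str = "elevation"):
    """Read an ESRI ASCII grid -> (masked array, GridDomain).

    ``expected`` names the variable for error messages (elevation,
    landcover, surface_soc).  Nodata cells come back masked; a
    malformed or missing header field raises a FormatError naming it.
    """
    path = Path(path)
    text = path.read_text().strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(
                    f"{expected} raster {path.name}: bad value for header "
                    f"field {parts[0]!r}"
                ) from exc
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(
                f"{expected} raster {path.name}: missing header field {key!r}"
            )
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    try:
        data = np.loadtxt(text[i:], ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{expected} raster {path.name}: bad data block") from exc
    if data.shape != (nrows, ncols):
        raise FormatError(
            f"{expected} raster {path.name}: data block {data.shape} does not "
            f"match header ({nrows}, {ncols})"
        )
    domain = GridDomain(nrows, ncols, header["cellsize"])
    return np.ma.masked_equal(data, nodata), domain


def write_forcing(path, forcing: pd.DataFrame) -> None:
    """Write a daily forcing table (ISO dates) as CSV."""
    df = forcing.copy()
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    atomic_write_text(path, df.to_csv(index=False))


def read_forcing(path) -> pd.DataFrame:
    """Read and validate a daily precipitation CSV.

    Requires ``date`` (ISO) and ``precip_mm`` columns; dates must be
    strictly consecutive days (duplicates, gaps — including a missing
    Feb 29 in a leap year — and negative amounts are rejected with the
    offending rows listed).
    """
    df = pd.read_csv(path)
    if "date" not in df or "precip_mm" not in df:
        raise ValidationError("forcing CSV needs 'date' and 'precip_mm' columns")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    dup = dates[dates.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate dates: {[str(d.date()) for d in dup[:5]]}")
    step = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    gaps = np.nonzero(step != 1)[0]
    if len(gaps):
        missing = [str((dates[g] + pd.Timedelta(days=1)).date()) for g in gaps[:5]]
        raise ValidationError(f"missing or out-of-order dates after: {missing}")
    neg = np.nonzero(df["precip_mm"].to_numpy() < 0)[0]
    if len(neg):
        rows = [int(i) + 2 for i in neg[:5]]  # 1-based, counting the header
        raise ValidationError(f"negative precipitation at rows {rows}")
    out = df.copy()
    out["date"] = dates
    return out


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(outdir, config_text: str, input_files=(), seeds=None,
                   started=None, version: str | None = None) -> Path:
    """Emit the run manifest (config digest, input checksums, seeds)."""
    from . import __version__

    outdir = Path(outdir)
    entries = []
    for f in input_files:
        f = Path(f)
        entries.append({"path": f.name, "sha256": _sha256(f.read_bytes())})
    manifest = {
        "software": "soilscape",
        "version": version or __version__,
        "config_sha256": _sha256(config_text.encode()),
        "inputs": entries,
        "seeds": seeds or {},
        "started": started or datetime.now(timezone.utc).isoformat(),
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=2) + "\n")
    return path
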