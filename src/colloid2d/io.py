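"""Reading and writing height maps and particle tables.

Supported image dialects:

* ``matrix-text`` — whitespace-delimited rows of heights (nm), one image row
  per line.
* ``tiff`` — single-channel TIFF with float or integer heights in nm.
* ``xyz`` — ``x y z`` triplets, one per line, sampling a regular grid.

Particle tables are CSV with header ``x_nm,y_nm,height_nm,area_nm2``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FormatError, HeightMap, Particle, PointPattern, ValidationError

PARTICLE_COLUMNS = ["x_nm", "y_nm", "height_nm", "area_nm2"]


def read_heightmap(path: str | Path, format: Optional[str] = None,
                   pixel_size: Optional[float] = None) -> HeightMap:
    """Read an AFM height map from disk.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``"matrix-text"``, ``"tiff"``, ``"xyz"``; guessed from the
        file suffix when omitted (``.tif``/``.tiff`` → tiff, ``.xyz`` → xyz,
        anything else → matrix-text).
    pixel_size
        Physical pixel size in nm/pixel.  Required for matrix-text and tiff;
        for xyz files it is inferred from the coordinate grid when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {"tif": "tiff", "tiff": "tiff", "xyz": "xyz"}.get(
            suffix.lstrip("."), "matrix-text")

    if format == "matrix-text":
        if pixel_size is None:
            raise ValidationError("pixel_size is required for matrix-text input")
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([float(tok) for tok in line.split()])
        if not rows:
            raise FormatError(f"{path}: no numeric rows")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
        return HeightMap(np.array(rows, dtype=float), float(pixel_size))

    if format == "tiff":
        if pixel_size is None:
            raise ValidationError("pixel_size is required for tiff input")
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a single-channel 2D TIFF")
        return HeightMap(np.asarray(arr, dtype=float), float(pixel_size))

    if format == "xyz":
        data = np.loadtxt(path, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise FormatError(f"{path}: expected three columns (x y z)")
        xs = np.unique(data[:, 0])
        ys = np.unique(data[:, 1])
        if xs.size * ys.size != data.shape[0]:
            raise FormatError(f"{path}: points do not sample a full regular grid")
        if pixel_size is None:
            steps = np.concatenate([np.diff(xs), np.diff(ys)])
            if steps.size == 0:
                raise FormatError(f"{path}: cannot infer pixel size from one sample")
            pixel_size = float(steps.mean())
            if not np.allclose(steps, pixel_size, rtol=1e-6):
                raise FormatError(f"{path}: irregular grid spacing")
        grid = np.full((ys.size, xs.size), np.nan)
        ix = np.searchsorted(xs, data[:, 0])
        iy = np.searchsorted(ys, data[:, 1])
        grid[iy, ix] = data[:, 2]
        if np.isnan(grid).any():
            raise FormatError(f"{path}: grid has missing samples")
        return HeightMap(grid, float(pixel_size))

    raise ValidationError(f"unknown height-map format: {format!r}")


def write_heightmap(map: HeightMap, path: str | Path,
                    format: Optional[str] = None) -> None:
    """Write a height map (inverse of :func:`read_heightmap`)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"tif": "tiff", "tiff": "tiff", "xyz": "xyz"}.get(suffix, "matrix-text")
    if format == "matrix-text":
        np.savetxt(path, map.heights, fmt="%.6g")
    elif format == "tiff":
        tifffile.imwrite(path, map.heights.astype(np.float32))
    elif format == "xyz":
        rows, cols = map.shape
        xv, yv = np.meshgrid(np.arange(cols), np.arange(rows))
        out = np.column_stack([
            xv.ravel() * map.pixel_size,
            yv.ravel() * map.pixel_size,
            map.heights.ravel(),
        ])
        np.savetxt(path, out, fmt="%.6g")
    else:
        raise ValidationError(f"unknown height-map format: {format!r}")


def particles_to_frame(particles: Iterable[Particle]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.x, p.y, p.height, p.area) for p in particles],
        columns=PARTICLE_COLUMNS,
    )


def write_particles(particles: Iterable[Particle], path: str | Path) -> None:
    particles_to_frame(particles).to_csv(path, index=False, float_format="%.6g")


def read_particles(path: str | Path) -> list[Particle]:
    df = pd.read_csv(path)
    missing = [c for c in PARTICLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "area_nm2" not in df.columns:
        df["area_nm2"] = 1.0
    return [
        Particle(x=row.x_nm, y=row.y_nm, height=row.height_nm, area=row.area_nm2)
        for row in df.itertuples()
    ]


def read_point_pattern(path: str | Path,
                       window: tuple[float, float]) -> PointPattern:
    """Load a particle CSV straight into a point pattern."""
    particles = read_particles(path)
    pts = np.array([(p.x, p.y) for p in particles], dtype=float).reshape(-1, 2)
    heights = np.array([p.height for p in particles], dtype=float)
    return PointPattern(points=pts, window=window, heights=heights)
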