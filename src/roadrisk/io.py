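"""Landscape table and raster IO.

Long-format cell tables travel as CSV or Parquet (by file suffix); grids
and covariate stacks travel as plain multi-band TIFF with a JSON band
manifest embedded in the image description (the synthetic world is
planar, so no georeferencing is attached).  Reads validate the schema and
report violations with row/column context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Landscape, table_to_grid

__all__ = [
    "write_landscape",
    "read_landscape",
    "write_raster",
    "read_raster",
    "export_covariate_rasters",
]

REQUIRED_COLUMNS = ("cell_id", "region", "row", "col")
RESPONSE_COLUMNS = ("road_present", "impact_present")


def write_landscape(table: pd.DataFrame, path) -> Path:
    """Write a landscape table to CSV or Parquet, chosen by suffix."""
    path = Path(path)
    if path.suffix == ".csv":
        table.to_csv(path, index=False)
    elif path.suffix in (".parquet", ".pq"):
        table.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported table format {path.suffix!r}")
    return path


def read_landscape(path) -> pd.DataFrame:
    """Read and validate a landscape table.

    Checks the required identifier columns, uniqueness of cell ids,
    in-bounds row/col, and that any response columns present are strictly
    binary — naming the offending rows.
    """
    path = Path(path)
    if path.suffix == ".csv":
        table = pd.read_csv(path)
    elif path.suffix in (".parquet", ".pq"):
        table = pd.read_parquet(path)
    else:
        raise ValueError(f"unsupported table format {path.suffix!r}")
    return validate_landscape_table(table)


def validate_landscape_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"landscape table missing required columns: {missing}")
    if table["cell_id"].duplicated().any():
        dupes = table.loc[table["cell_id"].duplicated(), "cell_id"].head(5).tolist()
        raise ValueError(f"duplicate cell_ids, e.g. {dupes}")
    if (table["row"] < 0).any() or (table["col"] < 0).any():
        bad = table.index[(table["row"] < 0) | (table["col"] < 0)][:5].tolist()
        raise ValueError(f"negative row/col at rows {bad}")
    for col in RESPONSE_COLUMNS:
        if col in table.columns:
            values = table[col].dropna()
            bad_mask = ~values.isin([0, 1])
            if bad_mask.any():
                rows = values.index[bad_mask][:5].tolist()
                raise ValueError(
                    f"non-binary values in response column {col!r} at rows {rows}"
                )
    return table


def write_raster(path, bands: dict) -> Path:
    """Write named 2D float bands as a multi-band TIFF.

    Band order and names are recorded in a JSON manifest in the image
    description, so :func:`read_raster` round-trips losslessly.
    """
    path = Path(path)
    names = list(bands)
    stack = np.stack([np.asarray(bands[n], dtype=np.float64) for n in names])
    tifffile.imwrite(
        path, stack, description=json.dumps({"bands": names}), photometric="minisblack"
    )
    return path


def read_raster(path) -> dict:
    """Read a multi-band TIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        manifest = json.loads(desc.value) if desc is not None else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = manifest.get("bands", [f"band_{i}" for i in range(stack.shape[0])])
    return {name: stack[i] for i, name in enumerate(names)}


def export_covariate_rasters(landscape: Landscape, out_dir) -> list:
    """One multi-band TIFF per region, one band per continuous covariate."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    continuous = [
        c for c, f in landscape.forms.items() if f != "categorical-blocks"
    ]
    for region, shape in landscape.grid_shapes.items():
        bands = {
            c: table_to_grid(landscape.table, region, c, shape) for c in continuous
        }
        written.append(write_raster(out_dir / f"{region}_covariates.tif", bands))
    return written
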