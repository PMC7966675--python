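"""Read/write helpers for the pipeline's standard formats.

Grids travel as CF-style NetCDF (dimensions time/lat/lon) through xarray's
scipy backend; tables are plain CSV; specs and configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr
import yaml


def write_grid(ds: xr.Dataset | xr.DataArray, path: str | Path) -> None:
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds.to_netcdf(path, engine="scipy")


def read_grid(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
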