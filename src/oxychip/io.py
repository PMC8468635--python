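"""File formats: YAML/JSON configs, HDF5 grids/fields, TIFF masks, CSV tracks.

All configuration quantities are SI (meters, seconds, mol/m^3); the track
CSV convention follows common tracking exports (columns cell_id, t_s,
x_um, y_um, micrometers).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .device_geometry import DeviceGeometry, RegionGrid, build_geometry
from .image_quant import LumenMask
from .oxygen_kinetics import KineticsParams
from .rd_solver import OxygenField, TransientResult


def load_config(path) -> tuple[DeviceGeometry, KineticsParams]:
    """Read a device configuration (YAML or JSON, sections geometry/kinetics).

    Missing sections or entries fall back to the device defaults.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    geom = build_geometry(data.get("geometry", {}))
    kin = KineticsParams(**(data.get("kinetics", {}) or {}))
    return geom, kin


def dump_config(geom: DeviceGeometry, params: KineticsParams, path) -> None:
    data = {"geometry": asdict(geom), "kinetics": asdict(params)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_grid(grid: RegionGrid, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.create_dataset("dirichlet", data=grid.dirichlet, compression="gzip")
        f.attrs["spacing"] = grid.spacing
        f.attrs["mode"] = grid.mode
        if grid.geometry is not None:
            f.attrs["geometry"] = json.dumps(asdict(grid.geometry))


def load_grid(path) -> RegionGrid:
    with h5py.File(path, "r") as f:
        geom = None
        if "geometry" in f.attrs:
            geom = DeviceGeometry(**json.loads(f.attrs["geometry"]))
        return RegionGrid(
            labels=f["labels"][...],
            spacing=float(f.attrs["spacing"]),
            mode=str(f.attrs["mode"]),
            dirichlet=f["dirichlet"][...],
            geometry=geom,
        )


def save_fields(result: TransientResult, path, grid_key: str = "grid") -> None:
    """Store a transient series (or a single steady field) with its grid."""
    with h5py.File(path, "w") as f:
        g = f.create_group(grid_key)
        grid = result.fields[0].grid
        g.create_dataset("labels", data=grid.labels, compression="gzip")
        g.create_dataset("dirichlet", data=grid.dirichlet, compression="gzip")
        g.attrs["spacing"] = grid.spacing
        g.attrs["mode"] = grid.mode
        if grid.geometry is not None:
            g.attrs["geometry"] = json.dumps(asdict(grid.geometry))
        f.create_dataset("t", data=result.times)
        f.create_dataset(
            "C", data=np.stack([fld.C for fld in result.fields]), compression="gzip"
        )


def load_fields(path, grid_key: str = "grid") -> TransientResult:
    with h5py.File(path, "r") as f:
        g = f[grid_key]
        geom = None
        if "geometry" in g.attrs:
            geom = DeviceGeometry(**json.loads(g.attrs["geometry"]))
        grid = RegionGrid(
            labels=g["labels"][...],
            spacing=float(g.attrs["spacing"]),
            mode=str(g.attrs["mode"]),
            dirichlet=g["dirichlet"][...],
            geometry=geom,
        )
        times = f["t"][...]
        C = f["C"][...]
    fields = [OxygenField(grid, C[k], t=float(times[k])) for k in range(len(times))]
    return TransientResult(times=times, fields=fields)


def write_mask(mask: LumenMask, path) -> None:
    tifffile.imwrite(path, mask.pixels.astype(np.uint8) * 255)


def read_mask(path, pixel_size: float, day: int = 0) -> LumenMask:
    px = tifffile.imread(path)
    return LumenMask(pixels=px > 0, pixel_size=pixel_size, day=day)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a track table (SI columns cell_id/t/x/y) as cell_id,t_s,x_um,y_um."""
    out = pd.DataFrame(
        {
            "cell_id": tracks["cell_id"],
            "t_s": tracks["t"],
            "x_um": tracks["x"] * 1e6,
            "y_um": tracks["y"] * 1e6,
        }
    )
    out.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    return pd.DataFrame(
        {
            "cell_id": raw["cell_id"],
            "t": raw["t_s"],
            "x": raw["x_um"] * 1e-6,
            "y": raw["y_um"] * 1e-6,
        }
    )
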