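"""Writers for the standard output formats: CSV time series, legacy-VTK and
HDF5 field containers, JSON summaries and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import h5py
import numpy as np
import pandas as pd

from .meshing import VoxelGrid

__all__ = ["write_vtk_rectilinear", "write_fields_h5", "write_timeseries_csv",
           "write_summary_json", "RunManifest"]


def write_vtk_rectilinear(path, grid: VoxelGrid, cell_data: Dict[str, np.ndarray],
                          title: str = "pulseheat fields") -> None:
    """Write per-voxel scalar fields as a legacy ASCII VTK rectilinear grid.

    Boolean masks are written as 0/1 integers; everything else as doubles.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    lines: List[str] = [
        "# vtk DataFile Version 3.0", title, "ASCII", "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
    ]
    for name, edges in (("X_COORDINATES", grid.x_edges),
                        ("Y_COORDINATES", grid.y_edges),
                        ("Z_COORDINATES", grid.z_edges)):
        lines.append(f"{name} {edges.size} double")
        lines.append(" ".join(f"{v:.9g}" for v in edges))
    lines.append(f"CELL_DATA {nx * ny * nz}")
    for name, values in cell_data.items():
        arr = np.asarray(values)
        if arr.shape != grid.shape:
            raise ValueError(f"cell data '{name}' shape {arr.shape} does not "
                             f"match grid {grid.shape}")
        # VTK cell data runs x fastest
        flat = np.transpose(arr, (2, 1, 0)).ravel()
        if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            body = " ".join(str(int(v)) for v in flat)
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            body = " ".join("nan" if np.isnan(v) else f"{v:.9g}" for v in flat)
        lines.append(body)
    path.write_text("\n".join(lines) + "\n")


def write_fields_h5(path, grid: VoxelGrid, fields: Dict[str, np.ndarray],
                    attrs: Dict | None = None) -> None:
    """HDF5 container with the grid edges and per-voxel fields."""
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.create_dataset("x_edges", data=grid.x_edges)
        g.create_dataset("y_edges", data=grid.y_edges)
        g.create_dataset("z_edges", data=grid.z_edges)
        g.create_dataset("material", data=grid.material)
        d = f.create_group("fields")
        for name, values in fields.items():
            d.create_dataset(name, data=np.asarray(values))
        for key, value in (attrs or {}).items():
            f.attrs[key] = value


def write_timeseries_csv(path, times, max_tumor, max_domain) -> None:
    pd.DataFrame({"time_s": times, "max_tumor_c": max_tumor,
                  "max_domain_c": max_domain}).to_csv(path, index=False)


def write_summary_json(path, summary: Dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


@dataclass
class RunManifest:
    """Inventory of one pipeline run: config identity, sizes and outputs."""

    config_sha1: str
    code_version: str
    n_cells: int
    mode: str
    wall_time_s: float
    outputs: List[str] = field(default_factory=list)

    @staticmethod
    def config_hash(config_text: str) -> str:
        return hashlib.sha1(config_text.encode()).hexdigest()

    def validate(self, base_dir: Path) -> None:
        """Every listed output must exist and be non-empty."""
        for name in self.outputs:
            p = base_dir / name
            if not p.exists() or p.stat().st_size == 0:
                raise FileNotFoundError(f"manifest output missing or empty: {name}")

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
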