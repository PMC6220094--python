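"""File formats: legacy-ASCII VTK export, HDF5 trajectories, CSV metrics,
run manifests.

VTK writing is a minimal legacy-format (v2.0 ASCII) implementation
covering exactly what the package emits: quadrilateral surface meshes with
per-domain scalars, and point clouds with per-cell scalars.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import REGIONS, CellLattice, SurfaceMesh, UnwrappedMap
from .simulator import TimeSeriesRecord


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VTK (legacy ASCII)
# ---------------------------------------------------------------------------

def write_vtk_mesh(mesh: SurfaceMesh, path: str | Path,
                   cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the quad surface as a legacy VTK unstructured grid.

    Per-domain scalar arrays in ``cell_data`` are written as CELL_DATA; the
    region label is always included.
    """
    a, c = mesh.domain_grid_shape
    pts = []
    offsets = []
    for s in range(3):
        offsets.append(sum(len(p) for p in pts))
        pts.append(mesh.vertices[s].reshape(-1, 3))
    points = np.concatenate(pts)
    quads = []
    for s in range(3):
        off = offsets[s]
        for i in range(a):
            for j in range(c):
                jp = (j + 1) % c
                quads.append([off + i * c + j, off + i * c + jp,
                              off + (i + 1) * c + jp, off + (i + 1) * c + j])
    quads = np.asarray(quads, dtype=np.int64)
    data = {"region": mesh.region_of_domain().astype(float)}
    if cell_data:
        data.update(cell_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write("vasowave bifurcation surface\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.9g")
        fh.write(f"CELLS {len(quads)} {len(quads) * 5}\n")
        np.savetxt(fh, np.column_stack([np.full(len(quads), 4), quads]), fmt="%d")
        fh.write(f"CELL_TYPES {len(quads)}\n")
        np.savetxt(fh, np.full(len(quads), 9), fmt="%d")   # VTK_QUAD
        fh.write(f"CELL_DATA {len(quads)}\n")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != len(quads):
                raise FormatError(
                    f"cell_data {name!r} has {arr.shape[0]} values for "
                    f"{len(quads)} domains")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")


def write_vtk_points(path: str | Path, points: np.ndarray,
                     scalars: dict[str, np.ndarray] | None = None) -> None:
    """Write a per-cell point cloud (polydata vertices) with scalar fields."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write("vasowave cell field\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, points, fmt="%.9g")
        fh.write(f"VERTICES {n} {2 * n}\n")
        np.savetxt(fh, np.column_stack([np.ones(n, dtype=int),
                                        np.arange(n)]), fmt="%d")
        if scalars:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in scalars.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape[0] != n:
                    raise FormatError(
                        f"scalar {name!r} has {arr.shape[0]} values for {n} points")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%.9g")


def write_unwrapped_csv(path: str | Path, lattice: CellLattice,
                        unwrap: UnwrappedMap,
                        fields: dict[str, np.ndarray] | None = None) -> None:
    """Per-cell flat-map CSV: cell_id, type, u, v, region (+ extra fields).

    Extra field arrays cover ECs first, then SMCs (length n_ec + n_smc).
    """
    n_ec, n_smc = lattice.n_ec, lattice.n_smc
    df = pd.DataFrame({
        "cell_id": np.concatenate([np.arange(n_ec), np.arange(n_smc)]),
        "type": ["ec"] * n_ec + ["smc"] * n_smc,
        "u": np.concatenate([unwrap.ec_uv[:, 0], unwrap.smc_uv[:, 0]]),
        "v": np.concatenate([unwrap.ec_uv[:, 1], unwrap.smc_uv[:, 1]]),
        "region": [REGIONS[r] for r in
                   np.concatenate([lattice.ec_region, lattice.smc_region])],
    })
    for name, arr in (fields or {}).items():
        if len(arr) != n_ec + n_smc:
            raise FormatError(f"field {name!r} must cover all cells (ECs then SMCs)")
        df[name] = arr
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# HDF5 trajectories
# ---------------------------------------------------------------------------

def save_record_h5(record: TimeSeriesRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=record.times)
        f.create_dataset("ec", data=record.ec, compression="gzip", shuffle=True)
        f.create_dataset("smc", data=record.smc, compression="gzip", shuffle=True)
        if record.final_state is not None:
            f.create_dataset("final_state", data=record.final_state)
            f.attrs["final_time"] = record.final_time
        f.attrs["metadata"] = json.dumps(record.metadata)


def load_record_h5(path: str | Path) -> TimeSeriesRecord:
    with h5py.File(path, "r") as f:
        final_state = f["final_state"][...] if "final_state" in f else None
        return TimeSeriesRecord(
            times=f["times"][...], ec=f["ec"][...], smc=f["smc"][...],
            metadata=json.loads(f.attrs.get("metadata", "{}")),
            final_state=final_state,
            final_time=float(f.attrs["final_time"]) if "final_time" in f.attrs
            else None)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance snapshot written next to every CLI output."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__
            self.software_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def save(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["platform"] = platform.platform()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
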