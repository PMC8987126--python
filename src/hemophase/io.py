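"""HDF5 container, JSON manifests and CSV series for pipeline round-trips.

The HDF5 container stores a whole cycle ensemble (float64) together with
its time grid, and optionally the mesh, wall surface, ROI assignments,
near-wall samples and ground truth of a synthetic dataset.  Manifests are
plain JSON: ``{period, n_cycles, n_phases, field_name, units, files}``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core_fields import (
    CycleEnsemble,
    FluidProperties,
    TimeGrid,
    VolumeMesh,
    WallSurface,
)
from .roi_analysis import ROIPartition
from .synthetic_data import GroundTruth, SyntheticDataset, SyntheticSpec

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "save_dataset",
    "load_dataset",
    "write_manifest",
    "read_manifest",
    "write_series_csv",
]

_FLOAT_FMT = "%.12e"


def _write_time_grid(group: h5py.Group, tg: TimeGrid) -> None:
    group.attrs["period"] = tg.period
    group.attrs["n_cycles"] = tg.n_cycles
    group.create_dataset("phase_times", data=tg.phase_times)


def _read_time_grid(group: h5py.Group) -> TimeGrid:
    return TimeGrid(
        period=float(group.attrs["period"]),
        phase_times=group["phase_times"][()],
        n_cycles=int(group.attrs["n_cycles"]),
    )


def save_ensemble(path: str | Path, ensemble: CycleEnsemble, group: str = "ensemble") -> None:
    """Write a cycle ensemble to an HDF5 file (float64, lossless)."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        _write_time_grid(g, ensemble.time_grid)
        g.create_dataset("values", data=ensemble.values, dtype="f8")
        g.attrs["units"] = ensemble.units
        g.attrs["name"] = ensemble.name
        g.attrs["location_kind"] = ensemble.location_kind


def load_ensemble(path: str | Path, group: str = "ensemble") -> CycleEnsemble:
    with h5py.File(path, "r") as f:
        g = f[group]
        return CycleEnsemble(
            time_grid=_read_time_grid(g),
            values=g["values"][()],
            units=str(g.attrs["units"]),
            name=str(g.attrs["name"]),
            location_kind=str(g.attrs["location_kind"]),
        )


def save_dataset(path: str | Path, ds: SyntheticDataset) -> None:
    """Write a full synthetic dataset (ensemble + geometry + truth)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    save_ensemble(path, ds.ensemble, group="ensemble")
    with h5py.File(path, "a") as f:
        f.attrs["spec"] = json.dumps(_spec_to_dict(ds.spec), sort_keys=True)
        f.create_dataset("near_wall", data=ds.near_wall, dtype="f8")

        m = f.create_group("mesh")
        m.create_dataset("node_coordinates", data=ds.mesh.node_coordinates)
        m.create_dataset("cell_connectivity", data=ds.mesh.cell_connectivity)
        m.create_dataset("cell_volumes", data=ds.mesh.cell_volumes)
        m.create_dataset("cell_centroids", data=ds.mesh.cell_centroids)
        m.attrs["structured_shape"] = ds.mesh.structured_shape
        m.attrs["periodic_axes"] = ds.mesh.periodic_axes

        w = f.create_group("wall")
        w.create_dataset("face_centres", data=ds.wall.face_centres)
        w.create_dataset("unit_normals", data=ds.wall.unit_normals)
        w.create_dataset("face_areas", data=ds.wall.face_areas)
        w.create_dataset("offsets", data=ds.wall.adjacent_sample_offsets)

        roi = f.create_group("roi")
        roi.create_dataset("cells", data=ds.roi.assignment)
        roi.create_dataset("faces", data=ds.roi_wall.assignment)
        roi.attrs["region_names"] = list(ds.roi.region_names)

        t = f.create_group("truth")
        t.create_dataset("wall_shear", data=ds.truth.wall_shear)
        t.create_dataset("sigma_envelope", data=ds.truth.sigma_envelope)
        t.create_dataset("sigma_window", data=ds.truth.sigma_window)
        t.create_dataset("mean_dissipation", data=ds.truth.mean_dissipation)
        t.attrs["seed"] = ds.truth.seed


def load_dataset(path: str | Path) -> SyntheticDataset:
    ensemble = load_ensemble(path, group="ensemble")
    with h5py.File(path, "r") as f:
        spec = _spec_from_dict(json.loads(f.attrs["spec"]))
        near_wall = f["near_wall"][()]
        m = f["mesh"]
        mesh = VolumeMesh(
            node_coordinates=m["node_coordinates"][()],
            cell_connectivity=m["cell_connectivity"][()],
            cell_volumes=m["cell_volumes"][()],
            cell_centroids=m["cell_centroids"][()],
            structured_shape=tuple(int(x) for x in m.attrs["structured_shape"]),
            periodic_axes=tuple(int(x) for x in m.attrs["periodic_axes"]),
        )
        w = f["wall"]
        wall = WallSurface(
            face_centres=w["face_centres"][()],
            unit_normals=w["unit_normals"][()],
            face_areas=w["face_areas"][()],
            adjacent_sample_offsets=w["offsets"][()],
        )
        roi_g = f["roi"]
        names = tuple(str(x) for x in roi_g.attrs["region_names"])
        roi = ROIPartition(region_names=names, assignment=roi_g["cells"][()])
        roi_wall = ROIPartition(region_names=names, assignment=roi_g["faces"][()])
        t = f["truth"]
        truth = GroundTruth(
            wall_shear=t["wall_shear"][()],
            sigma_envelope=t["sigma_envelope"][()],
            sigma_window=t["sigma_window"][()],
            mean_dissipation=t["mean_dissipation"][()],
            seed=int(t.attrs["seed"]),
        )
    return SyntheticDataset(
        spec=spec,
        time_grid=ensemble.time_grid,
        mesh=mesh,
        wall=wall,
        ensemble=ensemble,
        near_wall=near_wall,
        roi=roi,
        roi_wall=roi_wall,
        truth=truth,
    )


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["fluid"] = dataclasses.asdict(spec.fluid)
    d["harmonics"] = [list(h) for h in spec.harmonics]
    d["grid"] = list(spec.grid)
    return d


def _spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    d["fluid"] = FluidProperties(**d["fluid"])
    d["harmonics"] = tuple(tuple(h) for h in d["harmonics"])
    d["grid"] = tuple(d["grid"])
    return SyntheticSpec(**d)


def write_manifest(path: str | Path, time_grid: TimeGrid, field_name: str,
                   units: str, files: list[str]) -> None:
    payload = {
        "period": time_grid.period,
        "n_cycles": time_grid.n_cycles,
        "n_phases": time_grid.n_phases,
        "field_name": field_name,
        "units": units,
        "files": files,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_series_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
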