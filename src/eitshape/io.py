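"""File formats: HDF5 for meshes/datasets, CSV for measurements and masks,
JSON for phantoms and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .forward import MeasurementVector, measurement_pairs
from .mesh import TriMesh
from .phantoms import (
    Dataset,
    DatasetRecord,
    NormalizationStats,
    Phantom,
)

__all__ = [
    "save_mesh",
    "load_mesh",
    "export_mesh_text",
    "save_dataset",
    "load_dataset",
    "measurement_csv_header",
    "save_measurements_csv",
    "load_measurements_csv",
    "save_phantom_json",
    "load_phantom_json",
]


# -- meshes ---------------------------------------------------------------


def save_mesh(path: str | Path, mesh: TriMesh) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=mesh.nodes.astype(np.float64))
        f.create_dataset("triangles", data=mesh.triangles.astype(np.int64))
        f.create_dataset("boundary_nodes", data=mesh.boundary_nodes.astype(np.int64))
        f.create_dataset("electrode_nodes", data=mesh.electrode_nodes.astype(np.int64))
        f.attrs["h"] = mesh.h


def load_mesh(path: str | Path) -> TriMesh:
    with h5py.File(path, "r") as f:
        mesh = TriMesh(
            nodes=f["nodes"][()],
            triangles=f["triangles"][()],
            boundary_nodes=f["boundary_nodes"][()],
            electrode_nodes=f["electrode_nodes"][()],
            h=float(f.attrs["h"]),
        )
    mesh.validate()
    return mesh


def export_mesh_text(path: str | Path, mesh: TriMesh) -> None:
    """Plain-text node and triangle lists for inspection."""
    with open(path, "w") as f:
        f.write(f"# unit-disk mesh, h={mesh.h}\n")
        f.write(f"# nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.12g} {y:.12g}\n")
        f.write(f"# triangles {mesh.n_triangles}\n")
        for a, b, c in mesh.triangles:
            f.write(f"{a} {b} {c}\n")


# -- datasets -------------------------------------------------------------


def save_dataset(
    path: str | Path,
    dataset: Dataset,
    stats: NormalizationStats | None = None,
) -> None:
    """One HDF5 file per split: circle parameters, clean measurements,
    per-record seeds; a JSON sidecar carries config and normalisation."""
    path = Path(path)
    n = len(dataset)
    L = dataset.mesh.n_electrodes
    with h5py.File(path, "w") as f:
        g = f.create_group("phantoms")
        counts = np.array([r.phantom.n_anomalies for r in dataset.records])
        circ = np.full((n, 4, 4), np.nan)
        for i, r in enumerate(dataset.records):
            for j, c in enumerate(r.phantom.circles):
                circ[i, j] = (*c.center, c.radius, c.conductivity)
        g.create_dataset("n_anomalies", data=counts)
        g.create_dataset("circles", data=circ)
        f.create_dataset("measurements", data=dataset.measurement_matrix())
        f.create_dataset("seeds", data=np.array([r.seed for r in dataset.records]))
        f.attrs["master_seed"] = dataset.master_seed
        f.attrs["n_electrodes"] = L
        f.attrs["split"] = dataset.records[0].split if n else "train"
        f.attrs["mesh_h"] = dataset.mesh.h
    sidecar = {"master_seed": dataset.master_seed, "n_records": n}
    if stats is not None:
        sidecar["normalization"] = stats.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(path: str | Path, mesh: TriMesh) -> Dataset:
    from .phantoms import Circle

    with h5py.File(path, "r") as f:
        counts = f["phantoms/n_anomalies"][()]
        circ = f["phantoms/circles"][()]
        M = f["measurements"][()]
        seeds = f["seeds"][()]
        L = int(f.attrs["n_electrodes"])
        split = str(f.attrs["split"])
        master_seed = int(f.attrs["master_seed"])
    records = []
    for i in range(len(counts)):
        circles = [
            Circle((float(circ[i, j, 0]), float(circ[i, j, 1])),
                   float(circ[i, j, 2]), float(circ[i, j, 3]))
            for j in range(int(counts[i]))
        ]
        records.append(
            DatasetRecord(
                phantom=Phantom(circles=circles),
                measurements=MeasurementVector(M[i], n_electrodes=L),
                seed=int(seeds[i]),
                split=split,
            )
        )
    return Dataset(records=records, mesh=mesh, master_seed=master_seed)


# -- measurements as CSV --------------------------------------------------


def measurement_csv_header(L: int) -> list[str]:
    return [f"p{s}_d{k}" for s, k in measurement_pairs(L)]


def save_measurements_csv(
    path: str | Path, vectors: list[MeasurementVector]
) -> None:
    L = vectors[0].n_electrodes
    header = ",".join(measurement_csv_header(L))
    rows = [",".join(f"{v:.17g}" for v in m.values) for m in vectors]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")


def load_measurements_csv(path: str | Path, L: int) -> list[MeasurementVector]:
    lines = Path(path).read_text().strip().splitlines()
    return [
        MeasurementVector(np.array([float(x) for x in ln.split(",")]), L)
        for ln in lines[1:]
    ]


# -- phantoms as JSON -----------------------------------------------------


def save_phantom_json(path: str | Path, phantom: Phantom) -> None:
    Path(path).write_text(json.dumps(phantom.to_dict(), indent=1))


def load_phantom_json(path: str | Path) -> Phantom:
    return Phantom.from_dict(json.loads(Path(path).read_text()))
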