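"""Serialization: per-case JSON/CSV records, HDF5 tensor datasets, and a
plain-text legacy-VTK centerline export for visualisation.

A case on disk is ``<case_id>.json`` (scalars, branch specs, boundary
conditions, arch metadata) plus ``<case_id>.csv`` (per-point x, y, z,
radius, flow, and -- once solved -- the eight output channels).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import AortaGeometry, BranchSpec, FlowBC
from .oracle import HemodynamicProfile

_PROFILE_COLUMNS = {
    "p_mmHg": "pressure",
    "wss_Pa": "wss",
    "sfd": "sfd",
    "ke_mJkg": "ke",
    "tke_avg": "tke_avg",
    "tke_max": "tke_max",
    "v_avg": "v_avg",
    "v_max": "v_max",
}


def save_case(
    out_dir: str | Path,
    geometry: AortaGeometry,
    bc: FlowBC,
    profile: HemodynamicProfile | None = None,
) -> Path:
    """Write one case; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "case_id": geometry.case_id,
        "spacing_mm": geometry.spacing,
        "arch_height_mm": geometry.arch_height,
        "arch_width_mm": geometry.arch_width,
        "arch_start_index": geometry.arch_start_index,
        "arch_end_index": geometry.arch_end_index,
        "branches": [
            {"attach_index": b.attach_index, "outflow_fraction": b.outflow_fraction}
            for b in geometry.branches
        ],
        "inlet_flow_m3s": bc.inlet_flow,
        "inlet_pressure_mmHg": bc.inlet_pressure,
    }
    json_path = out_dir / f"{geometry.case_id}.json"
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))

    cols = {
        "x_mm": geometry.centerline_points[:, 0],
        "y_mm": geometry.centerline_points[:, 1],
        "z_mm": geometry.centerline_points[:, 2],
        "r_mm": geometry.radius,
    }
    if profile is not None:
        for col, attr in _PROFILE_COLUMNS.items():
            cols[col] = getattr(profile, attr)
    pd.DataFrame(cols).to_csv(out_dir / f"{geometry.case_id}.csv", index=False)
    return json_path


def load_case(
    directory: str | Path, case_id: str
) -> tuple[AortaGeometry, FlowBC, HemodynamicProfile | None, dict]:
    """Read one case back; returns (geometry, bc, profile-or-None, unknown_fields)."""
    directory = Path(directory)
    json_path = directory / f"{case_id}.json"
    csv_path = directory / f"{case_id}.csv"
    if not json_path.exists() or not csv_path.exists():
        raise DataError(f"case {case_id} not found in {directory}")
    meta = json.loads(json_path.read_text())
    known = {
        "case_id", "spacing_mm", "arch_height_mm", "arch_width_mm",
        "arch_start_index", "arch_end_index", "branches",
        "inlet_flow_m3s", "inlet_pressure_mmHg",
    }
    unknown = {k: v for k, v in meta.items() if k not in known}
    # round_trip parsing: the CSV holds shortest-repr float64 values and
    # the default (faster, 1-ulp) parser would break exact round-trips
    table = pd.read_csv(csv_path, float_precision="round_trip")
    geometry = AortaGeometry(
        case_id=meta["case_id"],
        centerline_points=table[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        spacing=meta["spacing_mm"],
        radius=table["r_mm"].to_numpy(),
        branches=[
            BranchSpec(b["attach_index"], b["outflow_fraction"])
            for b in meta["branches"]
        ],
        arch_height=meta["arch_height_mm"],
        arch_width=meta["arch_width_mm"],
        arch_start_index=meta["arch_start_index"],
        arch_end_index=meta["arch_end_index"],
    )
    bc = FlowBC(inlet_flow=meta["inlet_flow_m3s"])
    profile = None
    if set(_PROFILE_COLUMNS) <= set(table.columns):
        profile = HemodynamicProfile(
            **{attr: table[col].to_numpy() for col, attr in _PROFILE_COLUMNS.items()}
        )
    return geometry, bc, profile, unknown


def list_cases(directory: str | Path) -> list[str]:
    """Case ids present in a directory, sorted."""
    return sorted(p.stem for p in Path(directory).glob("*.json"))


def write_dataset_1d(
    path: str | Path,
    inputs: np.ndarray,
    outputs: np.ndarray,
    valid_lengths: np.ndarray,
    manifest: dict,
) -> None:
    """HDF5 container: inputs (C, 178, 7), outputs (C, 178, 8), valid_length (C)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=inputs, track_times=False)
        f.create_dataset("outputs", data=outputs, track_times=False)
        f.create_dataset("valid_length", data=valid_lengths, track_times=False)
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)


def read_dataset_1d(path: str | Path):
    with h5py.File(path, "r") as f:
        return (
            f["inputs"][...],
            f["outputs"][...],
            f["valid_length"][...],
            json.loads(f.attrs["manifest"]),
        )


def write_dataset_3d(
    path: str | Path,
    inputs: np.ndarray,
    outputs: np.ndarray,
    mask: np.ndarray,
    n_valid_planes: np.ndarray,
    manifest: dict,
) -> None:
    """HDF5 container: inputs (C, 48, 48, 80, 7), outputs (..., 1), bool mask."""
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=inputs, compression="gzip", track_times=False)
        f.create_dataset("outputs", data=outputs, compression="gzip", track_times=False)
        f.create_dataset("mask", data=mask, compression="gzip", track_times=False)
        f.create_dataset("n_valid_planes", data=n_valid_planes, track_times=False)
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)


def read_dataset_3d(path: str | Path):
    with h5py.File(path, "r") as f:
        return (
            f["inputs"][...],
            f["outputs"][...],
            f["mask"][...].astype(bool),
            f["n_valid_planes"][...],
            json.loads(f.attrs["manifest"]),
        )


def export_centerline_vtk(path: str | Path, geometry: AortaGeometry) -> None:
    """Write the centerline as legacy ASCII VTK polydata with radius scalars."""
    pts = geometry.centerline_points
    n = len(pts)
    lines = [
        "# vtk DataFile Version 3.0",
        f"centerline {geometry.case_id}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in pts]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    lines += [
        f"POINT_DATA {n}",
        "SCALARS radius float 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{r:.6f}" for r in geometry.radius]
    Path(path).write_text("\n".join(lines) + "\n")
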