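"""Dataset container: a directory with ``meta.json``, float arrays for the
task and rest recordings, and ``truth.json`` for synthetic data.

The container is the package's single interchange format; coordinates are
stored in millimeters in a right-handed RAS-like head frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import LeadField, SensorArray, SphericalHeadModel, VoxelGrid
from .signal import RawRecording

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    pass


def write_container(
    path,
    task: RawRecording,
    rest: RawRecording | None = None,
    head: SphericalHeadModel | None = None,
    truth: dict | None = None,
    leadfield: LeadField | None = None,
) -> Path:
    """Write a dataset directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "coordinate_frame": "head: RAS-like, x right, y anterior, z superior, mm",
        "sampling_rate_hz": task.fs,
        "channels": [
            {"name": n, "kind": str(k)} for n, k in zip(task.names, task.kinds)
        ],
        "head": head.to_dict() if head is not None else None,
        "sensors": task.sensors.to_dict() if task.sensors is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    np.save(path / "task.npy", task.data)
    if rest is not None:
        np.save(path / "rest.npy", rest.data)
    if truth is not None:
        (path / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    if leadfield is not None:
        np.save(path / "leadfield_gain.npy", leadfield.gain)
        lf_meta = {
            "names": list(leadfield.names),
            "kinds": [str(k) for k in leadfield.kinds],
            "grid": None
            if leadfield.grid is None
            else {
                "centers_mm": (1e3 * leadfield.grid.centers).tolist(),
                "spacing_mm": 1e3 * leadfield.grid.spacing,
                "ijk": leadfield.grid.ijk.tolist(),
                "origin_mm": (1e3 * leadfield.grid.origin).tolist(),
            },
        }
        (path / "leadfield_meta.json").write_text(json.dumps(lf_meta) + "\n")
    return path


def read_container(path) -> dict:
    """Read a dataset directory into recordings plus metadata.

    Returns a dict with keys task, rest, head, sensors, truth, meta.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"{path} is not a dataset container: missing meta.json")
    meta = json.loads(meta_path.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"container schema version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    names = [c["name"] for c in meta["channels"]]
    kinds = np.asarray([c["kind"] for c in meta["channels"]], dtype=object)
    fs = meta["sampling_rate_hz"]
    sensors = (
        SensorArray.from_dict(meta["sensors"]) if meta.get("sensors") else None
    )
    head = SphericalHeadModel.from_dict(meta["head"]) if meta.get("head") else None
    task = RawRecording(np.load(path / "task.npy"), fs, names, kinds, sensors)
    rest = None
    if (path / "rest.npy").exists():
        rest = RawRecording(np.load(path / "rest.npy"), fs, list(names), kinds.copy(), sensors)
    truth = None
    if (path / "truth.json").exists():
        truth = json.loads((path / "truth.json").read_text())
    leadfield = None
    if (path / "leadfield_gain.npy").exists():
        lf_meta = json.loads((path / "leadfield_meta.json").read_text())
        grid = None
        if lf_meta.get("grid"):
            g = lf_meta["grid"]
            grid = VoxelGrid(
                centers=np.asarray(g["centers_mm"], float) / 1e3,
                spacing=g["spacing_mm"] / 1e3,
                ijk=np.asarray(g["ijk"], int),
                origin=np.asarray(g["origin_mm"], float) / 1e3,
            )
        leadfield = LeadField(
            gain=np.load(path / "leadfield_gain.npy"),
            grid=grid,
            names=list(lf_meta["names"]),
            kinds=np.asarray(lf_meta["kinds"], dtype=object),
        )
    return {
        "task": task, "rest": rest, "head": head, "sensors": sensors,
        "truth": truth, "meta": meta, "leadfield": leadfield,
    }
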