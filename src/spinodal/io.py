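"""File formats, configuration and the reproducible pipeline runner.

Canonical on-disk formats:

* **volumes** (phase fields and binary structures): a raw little-endian
  array file plus a JSON sidecar carrying shape, dtype, voxel spacing, kind
  and provenance — nothing is guessed from the binary blob;
* **trajectories / datasets**: HDF5 (one dataset per save, parameters as
  attributes);
* **VTK legacy ASCII image data**: interoperable export for visualization;
* component reports, networks, tensors, screening results: JSON.

``run_pipeline`` executes a declarative multi-stage configuration
(simulate -> extract -> morph) and writes a manifest with the config hash,
per-stage outputs, checksums and wall times, so a run can be replayed and
verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .cahn_hilliard import CHParams, Trajectory, simulate
from .fields import UniformInitSpec, init_uniform
from .grids import GridSpec, PhaseField, ValidationError, VoxelStructure
from .morphology import count_connected, filter_artifacts, threshold_extract

__all__ = [
    "write_volume",
    "read_volume",
    "write_vtk",
    "save_trajectory",
    "load_trajectory",
    "RunConfig",
    "run_pipeline",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: Union[str, Path],
                 obj: Union[PhaseField, VoxelStructure]) -> Path:
    """Raw little-endian array + JSON sidecar; returns the data path."""
    path = Path(path)
    if isinstance(obj, PhaseField):
        data = obj.values.astype("<f8")
        meta = {"kind": "phase_field", "dtype": "<f8",
                "time_index": obj.time_index}
    elif isinstance(obj, VoxelStructure):
        data = obj.solid.astype("u1")
        meta = {"kind": "structure", "dtype": "u1",
                "provenance": _jsonable(obj.provenance)}
    else:
        raise ValidationError(f"cannot serialize {type(obj).__name__}")
    meta.update(shape=list(data.shape), spacing=obj.grid.spacing,
                periodic=obj.grid.periodic)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.tofile(path)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: Union[str, Path]) -> Union[PhaseField, VoxelStructure]:
    """Round-trip inverse of :func:`write_volume` (bit-exact)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(
            f"missing sidecar {sidecar}: volumes are never read without "
            "explicit metadata")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(path, dtype=meta["dtype"])
    if data.size != int(np.prod(shape)):
        raise ValidationError(
            f"data size {data.size} does not match sidecar shape {shape}")
    data = data.reshape(shape)
    grid = GridSpec(shape, spacing=meta["spacing"],
                    periodic=meta.get("periodic", True))
    if meta["kind"] == "phase_field":
        return PhaseField(data, grid, time_index=meta.get("time_index", 0))
    if meta["kind"] == "structure":
        return VoxelStructure(data.astype(bool), grid,
                              meta.get("provenance", {}))
    raise ValidationError(f"unknown volume kind {meta['kind']!r}")


def write_vtk(path: Union[str, Path],
              obj: Union[PhaseField, VoxelStructure],
              name: str = "field") -> Path:
    """Legacy ASCII VTK structured-points export (plain text)."""
    path = Path(path)
    if isinstance(obj, PhaseField):
        data = obj.values
    else:
        data = obj.solid.astype(np.uint8)
    nx, ny, nz = data.shape
    sp = obj.grid.spacing
    lines = [
        "# vtk DataFile Version 3.0", "spinodal volume", "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {sp} {sp} {sp}",
        f"POINT_DATA {data.size}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK expects x varying fastest
    flat = np.transpose(data, (2, 1, 0)).ravel()
    lines.extend(" ".join(f"{v:g}" for v in flat[k:k + 9])
                 for k in range(0, flat.size, 9))
    path.write_text("\n".join(lines) + "\n")
    return path


def save_trajectory(path: Union[str, Path], traj: Trajectory) -> Path:
    """HDF5 container: one dataset per save + params as attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        grp = f.create_group("saves")
        for field in traj.saves:
            grp.create_dataset(f"{field.time_index:05d}", data=field.values,
                               compression="gzip", compression_opts=1)
        pgrp = f.create_group("params")
        for k, v in asdict(traj.params).items():
            pgrp.attrs[k] = v
        f.attrs["spacing"] = traj.saves[0].grid.spacing
        if traj.init_spec is not None:
            f.attrs["init_spec"] = json.dumps(_jsonable(traj.init_spec))
    return path


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    with h5py.File(path, "r") as f:
        params = CHParams(**{k: v.item() if hasattr(v, "item") else v
                             for k, v in f["params"].attrs.items()})
        spacing = float(f.attrs["spacing"])
        saves = []
        for key in sorted(f["saves"]):
            data = f["saves"][key][...]
            grid = GridSpec(data.shape, spacing=spacing)
            saves.append(PhaseField(data, grid, time_index=int(key)))
        init_spec = json.loads(f.attrs["init_spec"]) if "init_spec" in f.attrs else None
    return Trajectory(saves, params, init_spec)


def _jsonable(obj):
    """Best-effort conversion of specs/arrays to JSON-safe values."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if obj.size > 64:
            return {"__array__": True, "shape": list(obj.shape),
                    "sha256": hashlib.sha256(np.ascontiguousarray(obj)).hexdigest()}
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# declarative pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("simulate", "extract", "morph")


class RunConfig:
    """Validated declarative run description.

    Required layout::

        {"seed": int,                  # explicit; no silent default
         "out_dir": str,
         "grid_shape": [nx, ny, nz],
         "init": {"mu": float, "width": float},
         "params": {... CHParams overrides ...},
         "stages": ["simulate", "extract", "morph"],
         "threshold": 0.0, "min_volume": 1000}
    """

    def __init__(self, raw: dict):
        if "seed" not in raw:
            raise ValidationError("config must set an explicit seed")
        if "out_dir" not in raw:
            raise ValidationError("config must set out_dir")
        stages = raw.get("stages", list(_KNOWN_STAGES))
        unknown = [s for s in stages if s not in _KNOWN_STAGES]
        if unknown:
            raise ValidationError(f"unknown stages {unknown}; known: {_KNOWN_STAGES}")
        order = [s for s in _KNOWN_STAGES if s in stages]
        if order != stages:
            raise ValidationError(f"stages must appear in dependency order {order}")
        self.raw = dict(raw)
        self.seed = int(raw["seed"])
        self.out_dir = Path(raw["out_dir"])
        self.stages = stages
        self.grid_shape = tuple(raw.get("grid_shape", (64, 64, 64)))
        self.init = dict(raw.get("init", {}))
        self.params = CHParams(**raw.get("params", {}))
        self.threshold = float(raw.get("threshold", 0.0))
        self.min_volume = int(raw.get("min_volume", 1000))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_jsonable(self.raw), sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Union[RunConfig, dict]) -> dict:
    """Execute the configured stages in order and write a manifest.

    Reruns with an identical config reproduce every output bit for bit
    (the solver is deterministic and all randomness is seeded).  On stage
    failure the manifest records the partial completion and the failing
    stage before the exception propagates.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    import spinodal

    manifest = {
        "config": _jsonable(config.raw),
        "config_hash": config.config_hash,
        "version": spinodal.__version__,
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            outputs = _run_stage(stage, config, state, out)
            manifest["stages"][stage] = {
                "outputs": {k: {"path": str(p), "sha256": _checksum(p)}
                            for k, p in outputs.items()},
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> dict:
    if stage == "simulate":
        grid = config.params.make_grid(config.grid_shape)
        spec = UniformInitSpec(mu=config.init.get("mu", 0.0),
                               width=config.init.get("width", 0.3),
                               seed=config.seed)
        traj = simulate(init_uniform(grid, spec), config.params, init_spec=spec)
        state["trajectory"] = traj
        path = save_trajectory(out / "trajectory.h5", traj)
        return {"trajectory": path}
    if stage == "extract":
        traj = state.get("trajectory")
        if traj is None:
            raise ValidationError("extract requires the simulate stage")
        structure = threshold_extract(traj[len(traj) - 1], config.threshold)
        structure = filter_artifacts(structure, config.min_volume)
        state["structure"] = structure
        path = write_volume(out / "structure.raw", structure)
        return {"structure": path}
    if stage == "morph":
        structure = state.get("structure")
        if structure is None:
            raise ValidationError("morph requires the extract stage")
        from .morphology import local_thickness, two_point_statistics

        report = count_connected(structure)
        s2 = two_point_statistics(structure, "solid")
        lt = local_thickness(structure, "pore")
        morph = {
            "porosity": structure.porosity,
            "n_solid_components": report.n_solid_components,
            "n_pore_components": report.n_pore_components,
            "mean_pore_radius_voxels": lt.mean,
            "s2_first_zero_crossing_voxels": s2.first_zero_crossing(),
        }
        path = out / "morphology.json"
        path.write_text(json.dumps(morph, indent=1))
        return {"morphology": path}
    raise ValidationError(f"unknown stage {stage!r}")
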