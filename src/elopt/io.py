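"""Case and report I/O.

A case directory holds a YAML manifest (format version, grid, structures as
flat-index lists, prescription), a ``spots.csv`` table, and one Matrix Market
coordinate file per energy layer (``layer_000.mtx`` ...).  Matrix data
round-trips bit-exactly (full double precision).  Scenario sets live in
``scenario_XX/`` subdirectories with their weights recorded in the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from .cases import (
    Case,
    CaseConfig,
    DoseInfluence,
    ScenarioSet,
    SpotLayout,
    Structure,
    StructureSet,
    VoxelGrid,
)

__all__ = ["write_case", "read_case", "write_scenarios", "read_scenarios",
           "write_report", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _layer_fname(i: int) -> str:
    return f"layer_{i:03d}.mtx"


def _write_influence(influence: DoseInfluence, path: Path) -> None:
    for i, block in enumerate(influence.blocks):
        sio.mmwrite(path / _layer_fname(i), sparse.coo_matrix(block), precision=17)


def _read_influence(path: Path, layer_ids, n_spots_per_layer) -> DoseInfluence:
    blocks = []
    for i, expected_cols in enumerate(n_spots_per_layer):
        f = path / _layer_fname(i)
        if not f.exists():
            raise FileNotFoundError(
                f"manifest lists layer {i} but {f.name} is missing"
            )
        block = sparse.csr_matrix(sio.mmread(f))
        if block.shape[1] != expected_cols:
            raise ValueError(
                f"layer {i}: {block.shape[1]} columns on disk, "
                f"{expected_cols} in the manifest"
            )
        blocks.append(block)
    return DoseInfluence(blocks, list(layer_ids), list(n_spots_per_layer))


def write_case(case: Case, path) -> Path:
    """Write a case directory (manifest.yaml, spots.csv, layers.csv, *.mtx)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "prescription": float(case.prescription),
        "grid": {
            "shape": [int(v) for v in case.grid.shape],
            "spacing_mm": [float(v) for v in case.grid.spacing_mm],
            "origin_mm": [float(v) for v in case.grid.origin_mm],
        },
        "structures": [
            {"name": s.name, "role": s.role,
             "voxel_indices": [int(i) for i in s.voxel_indices]}
            for s in case.structures
        ],
        "layers": {
            "layer_ids": [int(i) for i in case.influence.layer_ids],
            "n_spots_per_layer": [int(c) for c in case.influence.n_spots_per_layer],
        },
        "seed": int(case.config.seed),
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    case.spots.spots.to_csv(path / "spots.csv", index=False)
    case.spots.layers.to_csv(path / "layers.csv", index=False)
    _write_influence(case.influence, path)
    return path


def read_case(path) -> Case:
    """Read and validate a case directory written by :func:`write_case`."""
    path = Path(path)
    mf = path / "manifest.yaml"
    if not mf.exists():
        raise FileNotFoundError(f"no manifest.yaml under {path}")
    with open(mf) as fh:
        manifest = yaml.safe_load(fh)
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported case format version {version!r}")
    g = manifest["grid"]
    grid = VoxelGrid(tuple(g["shape"]), tuple(g["spacing_mm"]), tuple(g["origin_mm"]))
    structures = StructureSet(
        [Structure(s["name"], np.asarray(s["voxel_indices"], dtype=np.int64),
                   s["role"]) for s in manifest["structures"]],
        grid,
    )
    spots = pd.read_csv(path / "spots.csv")
    layers = pd.read_csv(path / "layers.csv")
    layout = SpotLayout(spots, layers)
    lay = manifest["layers"]
    influence = _read_influence(path, lay["layer_ids"], lay["n_spots_per_layer"])
    if influence.n_voxels != grid.n_voxels:
        raise ValueError(
            f"matrix rows ({influence.n_voxels}) do not match the grid "
            f"({grid.n_voxels} voxels)"
        )
    if influence.n_spots != len(spots):
        raise ValueError("spot table and matrix columns disagree")
    cfg = CaseConfig(grid_shape=tuple(g["shape"]), spacing_mm=g["spacing_mm"][0],
                     seed=int(manifest.get("seed", 0)))
    return Case(grid, structures, layout, influence, cfg,
                float(manifest.get("prescription", 100.0)))


def write_scenarios(scen: ScenarioSet, case: Case, path) -> Path:
    """Write a scenario set: the nominal case plus scenario_XX/ matrix dirs."""
    path = Path(path)
    write_case(case, path)
    for k, infl in enumerate(scen.scenarios):
        sub = path / f"scenario_{k:02d}"
        sub.mkdir(exist_ok=True)
        _write_influence(infl, sub)
    with open(path / "scenarios.yaml", "w") as fh:
        yaml.safe_dump(
            {"format_version": FORMAT_VERSION,
             "n_scenarios": scen.n_scenarios,
             "weights": [float(w) for w in scen.weights],
             "nominal_index": int(scen.nominal_index),
             "labels": list(scen.labels)},
            fh, sort_keys=False)
    return path


def read_scenarios(path) -> tuple[Case, ScenarioSet]:
    path = Path(path)
    case = read_case(path)
    with open(path / "scenarios.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported scenario format version")
    lay_ids = case.influence.layer_ids
    counts = case.influence.n_spots_per_layer
    scenarios = [
        _read_influence(path / f"scenario_{k:02d}", lay_ids, counts)
        for k in range(meta["n_scenarios"])
    ]
    return case, ScenarioSet(scenarios, np.asarray(meta["weights"], dtype=float),
                             int(meta["nominal_index"]), meta.get("labels", []))


def write_report(plan: dict, metrics: dict, times: dict, path,
                 dvh: dict | None = None) -> Path:
    """Write a machine-readable JSON report plus a human-readable table and
    optional DVH curves as CSV.

    ``plan`` must contain ``x`` (intensities) and may contain ``s``; the spot
    intensity table goes to ``plan.csv`` next to the report.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = {"metrics": metrics, "delivery_time": times}
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if "x" in plan and "layout" in plan:
        layout = plan["layout"]
        tbl = pd.DataFrame({
            "spot_id": layout.spots["spot_id"],
            "layer_id": layout.spots["layer_id"],
            "intensity": np.asarray(plan["x"], dtype=float),
        })
        tbl.to_csv(path.with_name(path.stem + "_plan.csv"), index=False)
    if dvh:
        frames = []
        for name, (bins, frac) in dvh.items():
            frames.append(pd.DataFrame(
                {"structure": name, "dose": bins, "volume_fraction": frac}))
        pd.concat(frames).to_csv(path.with_name(path.stem + "_dvh.csv"),
                                 index=False)
    lines = [f"{k:>24s} : {v:.4g}" if isinstance(v, (int, float)) else
             f"{k:>24s} : {v}" for k, v in {**metrics, **times}.items()]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path
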