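"""Synthetic pencil-beam-scanning cases: digital phantoms with per-energy-layer
sparse dose-influence matrices.

A *case* bundles a voxel grid, structures (target / organs at risk / body), a
spot layout grouped by (beam, energy layer), and one sparse dose-influence
block per layer.  The depth-dose model is an analytic Bragg-like curve (rising
entrance plateau, Gaussian peak at the nominal range, sharp distal falloff)
with Gaussian lateral spread; it is deliberately simple — the point is to
create realistic *layer redundancy*, the property energy-layer optimization
exploits, not to emulate a clinical dose engine.

All randomness (sub-millimetre spot jitter, per-spot calibration factors) is
drawn once from the case seed so that uncertainty scenarios regenerated from
the same geometry differ only by the prescribed setup shift / range scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "VoxelGrid",
    "Structure",
    "StructureSet",
    "SpotLayout",
    "DoseInfluence",
    "ScenarioSet",
    "CaseConfig",
    "Case",
    "CaseGenerationError",
    "generate_case",
    "generate_scenarios",
]


class CaseGenerationError(ValueError):
    """Raised when a requested phantom configuration is geometrically invalid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular dose grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis (nx, ny, nz).
    spacing_mm : tuple of float
        Voxel size per axis in mm (default 3 mm isotropic).
    origin_mm : tuple of float
        Position of the grid corner in mm.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("grid shape must be three counts >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacings must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-centre coordinates in mm (C order)."""
        axes = [
            self.origin_mm[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing_mm[k]
            for k in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass(frozen=True)
class Structure:
    """A region of interest as a set of flat voxel indices."""

    name: str
    voxel_indices: np.ndarray
    role: str  # 'target' | 'oar' | 'body'

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=np.int64)
        idx = np.unique(idx)
        object.__setattr__(self, "voxel_indices", idx)
        if self.role not in ("target", "oar", "body"):
            raise ValueError(f"unknown structure role {self.role!r}")
        if self.role == "target" and idx.size == 0:
            raise CaseGenerationError(f"target structure {self.name!r} is empty")

    @property
    def size(self) -> int:
        return int(self.voxel_indices.size)


class StructureSet:
    """Ordered collection of structures, addressable by name."""

    def __init__(self, structures: Sequence[Structure], grid: VoxelGrid):
        self.structures = list(structures)
        self._by_name = {s.name: s for s in self.structures}
        if len(self._by_name) != len(self.structures):
            raise ValueError("duplicate structure names")
        n = grid.n_voxels
        for s in self.structures:
            if s.voxel_indices.size and (
                s.voxel_indices.min() < 0 or s.voxel_indices.max() >= n
            ):
                raise CaseGenerationError(f"structure {s.name!r} outside the grid")
        self.grid = grid

    def __getitem__(self, name: str) -> Structure:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.structures)

    def __len__(self):
        return len(self.structures)

    @property
    def target(self) -> Structure:
        for s in self.structures:
            if s.role == "target":
                return s
        raise KeyError("no target structure")

    @property
    def body(self) -> Structure:
        for s in self.structures:
            if s.role == "body":
                return s
        raise KeyError("no body structure")


@dataclass
class SpotLayout:
    """Spot and layer bookkeeping tables.

    ``spots`` has one row per spot with columns
    ``spot_id, layer_id, beam_id, energy_index, x_mm, y_mm`` (lateral
    beam's-eye-view coordinates); spots are contiguous by (beam, layer).
    ``layers`` has one row per energy layer with columns
    ``layer_id, beam_id, energy_index, range_mm, n_spots``.
    """

    spots: pd.DataFrame
    layers: pd.DataFrame

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_slices(self) -> list[slice]:
        """Column slice of the stacked influence matrix for each layer."""
        counts = self.layers["n_spots"].to_numpy()
        offsets = np.concatenate([[0], np.cumsum(counts)])
        return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]


@dataclass
class DoseInfluence:
    """Per-layer sparse dose-influence blocks D_i (voxels x layer spots)."""

    blocks: list
    layer_ids: list
    n_spots_per_layer: list

    def __post_init__(self):
        if len(self.blocks) < 1:
            raise ValueError("at least one layer block required")
        rows = {b.shape[0] for b in self.blocks}
        if len(rows) != 1:
            raise ValueError("all layer blocks must share the voxel count")
        self._stacked = None

    @property
    def n_layers(self) -> int:
        return len(self.blocks)

    @property
    def n_voxels(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_spots(self) -> int:
        return int(sum(self.n_spots_per_layer))

    @property
    def stacked(self) -> sparse.csr_matrix:
        """Full influence matrix D = [D_1 ... D_N] (cached)."""
        if self._stacked is None:
            self._stacked = sparse.hstack(self.blocks, format="csr")
        return self._stacked

    def layer_slices(self) -> list[slice]:
        offsets = np.concatenate([[0], np.cumsum(self.n_spots_per_layer)])
        return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]

    def dose(self, x: np.ndarray) -> np.ndarray:
        return self.stacked @ np.asarray(x, dtype=float)


@dataclass
class ScenarioSet:
    """Uncertainty scenarios: one DoseInfluence per setup/range realisation."""

    scenarios: list
    weights: np.ndarray
    nominal_index: int = 0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("scenario weights must be nonnegative, not all zero")
        self.weights = w / w.sum()
        dims = {(s.n_voxels, s.n_spots) for s in self.scenarios}
        if len(dims) != 1:
            raise ValueError("scenarios must share dimensions")

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)

    @property
    def nominal(self) -> DoseInfluence:
        return self.scenarios[self.nominal_index]


@dataclass
class CaseConfig:
    """Phantom + beam configuration for :func:`generate_case`.

    The defaults describe a small mid-grid ellipsoidal target with one lateral
    cuboid organ at risk, two coplanar beams, 3 mm lateral / 5 mm longitudinal
    spot spacing on a 3 mm grid — small enough that full optimization
    pipelines run in seconds.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    spacing_mm: float = 3.0
    ctv_center_mm: tuple[float, float, float] | None = None
    ctv_radii_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    oar_boxes_mm: tuple = ((( -12.0, -9.0), (-9.0, 9.0), (-9.0, 9.0)),)
    beam_angles_deg: tuple = (0.0, 90.0)
    lateral_spacing_mm: float = 3.0
    longitudinal_spacing_mm: float = 5.0
    n_energies_per_beam: int | None = None
    sigma_lateral_mm: float = 4.0
    bragg_proximal_sigma_mm: float = 5.0
    bragg_distal_sigma_mm: float = 2.0
    entrance_plateau: float = 0.3
    plateau_rise: float = 0.4
    dose_cutoff_rel: float = 1e-3
    position_jitter_mm: float = 0.3
    calib_jitter: float = 0.05
    prescription: float = 100.0
    seed: int = 0


@dataclass
class Case:
    """A complete synthetic case; iterates as (grid, structures, spots, influence)."""

    grid: VoxelGrid
    structures: StructureSet
    spots: SpotLayout
    influence: DoseInfluence
    config: CaseConfig
    prescription: float = 100.0

    def __iter__(self):
        return iter((self.grid, self.structures, self.spots, self.influence))

    @property
    def n_layers(self) -> int:
        return self.influence.n_layers


# ---------------------------------------------------------------------------
# depth-dose and geometry helpers


def bragg_curve(depth_mm: np.ndarray, range_mm: float, cfg: CaseConfig) -> np.ndarray:
    """Analytic Bragg-like depth-dose: entrance plateau rising to a unit-height
    Gaussian peak at ``range_mm``, with a sharp Gaussian distal falloff.

    The curve's argmax sits exactly at the nominal range, so deeper energies
    produce strictly deeper peaks.
    """
    t = np.asarray(depth_mm, dtype=float)
    r = float(range_mm)
    rise = cfg.entrance_plateau + cfg.plateau_rise * np.clip(t / max(r, 1e-9), 0.0, 1.0)
    proximal = rise + np.exp(-0.5 * ((t - r) / cfg.bragg_proximal_sigma_mm) ** 2)
    peak_height = cfg.entrance_plateau + cfg.plateau_rise + 1.0
    distal = peak_height * np.exp(-0.5 * ((t - r) / cfg.bragg_distal_sigma_mm) ** 2)
    out = np.where(t <= r, proximal, distal)
    return np.where(t < 0, 0.0, out)


def _beam_frame(angle_deg: float):
    """Beam direction and lateral unit vectors for a coplanar gantry angle."""
    th = np.deg2rad(angle_deg)
    d = np.array([np.cos(th), np.sin(th), 0.0])
    u = np.array([-np.sin(th), np.cos(th), 0.0])  # lateral x (scanned fast)
    w = np.array([0.0, 0.0, 1.0])  # lateral y (line direction)
    return d, u, w


def _build_structures(grid: VoxelGrid, cfg: CaseConfig) -> StructureSet:
    centers = grid.voxel_centers()
    extent = np.array(grid.shape) * np.array(grid.spacing_mm)
    mid = np.array(grid.origin_mm) + extent / 2.0
    ctv_c = np.array(cfg.ctv_center_mm) if cfg.ctv_center_mm is not None else mid
    lo = np.array(grid.origin_mm)
    if np.any(ctv_c < lo) or np.any(ctv_c > lo + extent):
        raise CaseGenerationError("target centre lies outside the dose grid")
    radii = np.asarray(cfg.ctv_radii_mm, dtype=float)
    inside = np.sum(((centers - ctv_c) / radii) ** 2, axis=1) <= 1.0
    ctv_idx = np.flatnonzero(inside)
    if ctv_idx.size == 0:
        raise CaseGenerationError("target ellipsoid contains no voxels")

    structures = [Structure("CTV", ctv_idx, "target")]
    for k, box in enumerate(cfg.oar_boxes_mm):
        rel = centers - ctv_c
        mask = np.ones(len(centers), dtype=bool)
        for ax, (a, b) in enumerate(box):
            mask &= (rel[:, ax] >= a) & (rel[:, ax] <= b)
        mask[ctv_idx] = False
        name = "OAR" if len(cfg.oar_boxes_mm) == 1 else f"OAR{k + 1}"
        structures.append(Structure(name, np.flatnonzero(mask), "oar"))
    structures.append(Structure("BODY", np.arange(grid.n_voxels), "body"))
    return StructureSet(structures, grid)


def _plan_layout(grid, structures, cfg, rng):
    """Place energy layers and spots so every target voxel is reachable."""
    centers = grid.voxel_centers()
    ctv = structures.target
    ctv_pts = centers[ctv.voxel_indices]
    half_slab = cfg.longitudinal_spacing_mm / 2.0 + 1.0  # depth tolerance, mm

    spot_rows, layer_rows = [], []
    layer_id = 0
    for beam_id, angle in enumerate(cfg.beam_angles_deg):
        d, u, w = _beam_frame(angle)
        t0 = centers @ d
        t0_min = t0.min() - 0.5 * max(grid.spacing_mm)
        depth_ctv = ctv_pts @ d - t0_min
        dmin, dmax = depth_ctv.min(), depth_ctv.max()
        if cfg.n_energies_per_beam is None:
            n_e = int(np.floor((dmax - dmin) / cfg.longitudinal_spacing_mm)) + 1
        else:
            n_e = int(cfg.n_energies_per_beam)
            if n_e < 1:
                raise CaseGenerationError("n_energies_per_beam must be >= 1")
        span = (n_e - 1) * cfg.longitudinal_spacing_mm
        r_start = (dmin + dmax) / 2.0 - span / 2.0
        a_ctv = ctv_pts @ u
        b_ctv = ctv_pts @ w
        for e in range(n_e):
            r_e = r_start + e * cfg.longitudinal_spacing_mm
            in_slab = np.abs(depth_ctv - r_e) <= half_slab
            if not np.any(in_slab):
                raise CaseGenerationError(
                    f"beam {beam_id} (angle {angle} deg): energy index {e} "
                    f"(range {r_e:.1f} mm) covers no target voxels — no spots"
                )
            sa, sb = a_ctv[in_slab], b_ctv[in_slab]
            ga = np.arange(
                np.floor(sa.min() / cfg.lateral_spacing_mm),
                np.floor(sa.max() / cfg.lateral_spacing_mm) + 1,
            ) * cfg.lateral_spacing_mm
            gb = np.arange(
                np.floor(sb.min() / cfg.lateral_spacing_mm),
                np.floor(sb.max() / cfg.lateral_spacing_mm) + 1,
            ) * cfg.lateral_spacing_mm
            aa, bb = np.meshgrid(ga, gb, indexing="ij")
            pos = np.column_stack([aa.ravel(), bb.ravel()])
            # keep spots with a slab voxel within one lateral spacing + margin
            reach = cfg.lateral_spacing_mm + 1.0
            d2 = (
                (pos[:, 0][:, None] - sa[None, :]) ** 2
                + (pos[:, 1][:, None] - sb[None, :]) ** 2
            )
            keep = (d2.min(axis=1) <= reach**2)
            pos = pos[keep]
            if len(pos) == 0:
                raise CaseGenerationError(
                    f"beam {beam_id}: energy index {e} produced zero spots"
                )
            jit = rng.uniform(-cfg.position_jitter_mm, cfg.position_jitter_mm, pos.shape)
            pos = pos + jit
            for x_mm, y_mm in pos:
                spot_rows.append((layer_id, beam_id, e, x_mm, y_mm))
            layer_rows.append((layer_id, beam_id, e, r_e, len(pos)))
            layer_id += 1

    spots = pd.DataFrame(
        spot_rows, columns=["layer_id", "beam_id", "energy_index", "x_mm", "y_mm"]
    )
    spots.insert(0, "spot_id", np.arange(len(spots)))
    layers = pd.DataFrame(
        layer_rows, columns=["layer_id", "beam_id", "energy_index", "range_mm", "n_spots"]
    )
    calib = 1.0 + rng.uniform(-cfg.calib_jitter, cfg.calib_jitter, len(spots))
    return SpotLayout(spots, layers), calib


def _compute_influence(
    grid: VoxelGrid,
    layout: SpotLayout,
    calib: np.ndarray,
    cfg: CaseConfig,
    setup_shift_mm: np.ndarray | None = None,
    range_scale: float = 1.0,
) -> DoseInfluence:
    """Deposit dose for every spot; optional patient shift and range scaling
    produce uncertainty scenarios from the same geometry."""
    centers = grid.voxel_centers()
    if setup_shift_mm is not None:
        centers = centers + np.asarray(setup_shift_mm, dtype=float)

    blocks, layer_ids, counts = [], [], []
    spot_tbl = layout.spots
    for _, lay in layout.layers.iterrows():
        beam_id = int(lay["beam_id"])
        d, u, w = _beam_frame(cfg.beam_angles_deg[beam_id])
        # depth origin fixed by the *nominal* grid so shifts move the patient
        nominal_centers = grid.voxel_centers()
        t0_min = (nominal_centers @ d).min() - 0.5 * max(grid.spacing_mm)
        depth = centers @ d - t0_min
        a = centers @ u
        b = centers @ w
        r_e = float(lay["range_mm"]) * range_scale
        dd = bragg_curve(depth, r_e, cfg)
        rows_sel = spot_tbl["layer_id"] == int(lay["layer_id"])
        sub = spot_tbl[rows_sel]
        cols = []
        for sid, x_mm, y_mm in zip(sub["spot_id"], sub["x_mm"], sub["y_mm"]):
            lat2 = (a - x_mm) ** 2 + (b - y_mm) ** 2
            col = dd * np.exp(-0.5 * lat2 / cfg.sigma_lateral_mm**2) * calib[sid]
            col[col < cfg.dose_cutoff_rel * col.max()] = 0.0
            cols.append(sparse.csr_matrix(col.reshape(-1, 1)))
        blocks.append(sparse.hstack(cols, format="csr"))
        layer_ids.append(int(lay["layer_id"]))
        counts.append(len(sub))
    return DoseInfluence(blocks, layer_ids, counts)


def generate_case(config: CaseConfig | None = None, seed: int | None = None) -> Case:
    """Generate a seeded synthetic PBS case.

    Deterministic for a fixed config + seed.  Raises
    :class:`CaseGenerationError` when the target falls outside the grid, a
    requested layer would carry zero spots, or some target voxel receives no
    dose influence.
    """
    cfg = config if config is not None else CaseConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    grid = VoxelGrid(tuple(int(n) for n in cfg.grid_shape), (cfg.spacing_mm,) * 3)
    structures = _build_structures(grid, cfg)
    layout, calib = _plan_layout(grid, structures, cfg, rng)
    influence = _compute_influence(grid, layout, calib, cfg)

    covered = influence.dose(np.ones(influence.n_spots))
    ctv_idx = structures.target.voxel_indices
    if np.any(covered[ctv_idx] <= 0):
        missing = int(np.sum(covered[ctv_idx] <= 0))
        raise CaseGenerationError(
            f"{missing} target voxels receive no dose influence; widen spot "
            "coverage (sigma_lateral_mm / lateral_spacing_mm)"
        )
    return Case(grid, structures, layout, influence, cfg, cfg.prescription)


def generate_scenarios(
    case: Case,
    setup_shift_mm: float,
    range_uncertainty_fraction: float,
    seed: int | None = None,
) -> ScenarioSet:
    """Robustness scenarios: nominal + 6 cardinal setup shifts + 2 range
    scalings when both uncertainties are positive (9 scenarios); degenerate
    uncertainties drop the corresponding scenarios (0/0 gives nominal only).

    Shifts move the patient (voxel grid) relative to the beams; range
    uncertainty rescales each layer's nominal range.  Weights are uniform.
    """
    if setup_shift_mm < 0 or range_uncertainty_fraction < 0:
        raise ValueError("uncertainty magnitudes must be nonnegative")
    cfg = case.config
    rng = np.random.default_rng(cfg.seed)
    # replay the layout RNG stream so calibration matches the nominal case
    _, calib = _plan_layout(case.grid, case.structures, cfg, rng)

    scenarios = [case.influence]
    labels = ["nominal"]
    if setup_shift_mm > 0:
        for ax in range(3):
            for sign in (+1.0, -1.0):
                shift = np.zeros(3)
                shift[ax] = sign * setup_shift_mm
                scenarios.append(
                    _compute_influence(case.grid, case.spots, calib, cfg, shift, 1.0)
                )
                labels.append(f"shift_{'xyz'[ax]}{'+' if sign > 0 else '-'}")
    if range_uncertainty_fraction > 0:
        for sign in (+1.0, -1.0):
            scale = 1.0 + sign * range_uncertainty_fraction
            scenarios.append(
                _compute_influence(case.grid, case.spots, calib, cfg, None, scale)
            )
            labels.append(f"range{'+' if sign > 0 else '-'}")
    weights = np.full(len(scenarios), 1.0 / len(scenarios))
    return ScenarioSet(scenarios, weights, nominal_index=0, labels=labels)
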