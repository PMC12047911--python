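"""DVH plan objective, iterative-convex-relaxation active sets, and plan-quality
metrics (conformity index, D95 normalization, DVH curves).

The plan objective is a weighted mean-squared deviation over *active* voxel
sets: L2 terms always penalize the whole structure, while DVH-max / DVH-min
terms penalize only the voxels currently violating the dose-volume limit
beyond the allowed fraction.  The active sets are refreshed from the current
dose each outer iteration (iterative convex relaxation), which turns the
nonconvex dose-volume constraints into a sequence of convex least-squares
problems.

Doses are expressed in percent of the prescription throughout (prescription
= 100 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import Structure, StructureSet

__all__ = [
    "ObjectiveTerm",
    "ActiveSets",
    "evaluate_objective",
    "update_active_sets",
    "conformity_index",
    "normalize_plan",
    "dvh_curve",
    "default_objectives",
]

_KINDS = ("L2", "DVH_max", "DVH_min")


@dataclass(frozen=True)
class ObjectiveTerm:
    """One term of the plan objective.

    kind
        'L2' (mean-squared deviation from ``dose_level`` over the whole
        structure), 'DVH_max' (at most ``volume_fraction`` of the structure
        may exceed ``dose_level``) or 'DVH_min' (at least ``volume_fraction``
        must reach ``dose_level``).
    weight
        Nonnegative objective weight omega.
    dose_level
        Prescribed / limit dose in percent of prescription.
    volume_fraction
        Allowed / required fraction in [0, 1]; DVH terms only.
    """

    kind: str
    structure: str
    weight: float
    dose_level: float
    volume_fraction: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("objective weight must be >= 0")
        if self.dose_level < 0:
            raise ValueError("dose level must be >= 0")
        if self.kind != "L2":
            if self.volume_fraction is None or not 0.0 <= self.volume_fraction <= 1.0:
                raise ValueError("DVH terms need volume_fraction in [0, 1]")


@dataclass
class ActiveSets:
    """Per-term active voxel index arrays (aligned with the term list)."""

    sets: list

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, i):
        return self.sets[i]

    def total_rows(self) -> int:
        return int(sum(len(s) for s in self.sets))


def evaluate_objective(
    dose: np.ndarray,
    terms: list[ObjectiveTerm],
    active: ActiveSets,
    structures: StructureSet,
) -> float:
    """f = sum over terms of (omega / |Omega|) * sum_{j in Omega} (d_j - level)^2.

    Empty active sets contribute zero.  Raises on indices outside the dose
    vector.
    """
    dose = np.asarray(dose, dtype=float)
    if len(active) != len(terms):
        raise ValueError("active sets not aligned with terms")
    f = 0.0
    for term, omega_set in zip(terms, active.sets):
        idx = np.asarray(omega_set, dtype=np.int64)
        if idx.size == 0 or term.weight == 0.0:
            continue
        if idx.min() < 0 or idx.max() >= dose.size:
            raise IndexError("active-set voxel index outside the dose grid")
        dev = dose[idx] - term.dose_level
        f += term.weight / idx.size * float(dev @ dev)
    return f


def _active_for_term(
    dose: np.ndarray, term: ObjectiveTerm, struct: Structure
) -> np.ndarray:
    idx = struct.voxel_indices
    d = dose[idx]
    if term.kind == "L2":
        return idx.copy()
    n = idx.size
    if term.kind == "DVH_max":
        allowed = int(np.floor(term.volume_fraction * n))
        violators = d > term.dose_level
        # excuse the `allowed` highest-dose voxels (ties broken by voxel index)
        order = np.lexsort((idx, -d))  # descending dose, ascending index
        excused = np.zeros(n, dtype=bool)
        excused[order[:allowed]] = True
        return idx[violators & ~excused]
    # DVH_min: fraction (1 - v) permitted below the level
    allowed = int(np.floor((1.0 - term.volume_fraction) * n))
    violators = d < term.dose_level
    order = np.lexsort((idx, d))  # ascending dose, ascending index
    excused = np.zeros(n, dtype=bool)
    excused[order[:allowed]] = True
    return idx[violators & ~excused]


def update_active_sets(
    dose: np.ndarray, terms: list[ObjectiveTerm], structures: StructureSet
) -> ActiveSets:
    """Iterative-convex-relaxation active-set map H evaluated at the current dose.

    L2 terms activate the full structure; DVH-max terms activate voxels above
    the limit except the floor(v*|S|) highest-dose voxels (the fraction allowed
    to exceed it); DVH-min terms mirror this below the level.  Tie-breaking is
    by ascending voxel index, so H is a deterministic function of the dose.
    """
    dose = np.asarray(dose, dtype=float)
    return ActiveSets(
        [_active_for_term(dose, t, structures[t.structure]) for t in terms]
    )


def conformity_index(
    dose: np.ndarray, ctv: Structure, body: Structure, prescription: float
) -> float:
    """CI = V100,CTV^2 / (V_CTV * V100): 1 for ideal conformity, 0 when no
    voxel reaches the prescription."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if ctv.size == 0:
        raise ValueError("empty CTV")
    dose = np.asarray(dose, dtype=float)
    v100_ctv = int(np.sum(dose[ctv.voxel_indices] >= prescription))
    v100 = int(np.sum(dose[body.voxel_indices] >= prescription))
    if v100 == 0:
        return 0.0
    return v100_ctv**2 / (ctv.size * v100)


def normalize_plan(
    x: np.ndarray, influence, ctv: Structure, prescription: float = 100.0
) -> np.ndarray:
    """Scale spot intensities so the CTV D95% equals the prescription.

    D95% is the dose received by at least 95% of the CTV, i.e. the 5th
    percentile of the CTV dose distribution.
    """
    x = np.asarray(x, dtype=float)
    dose = influence.dose(x)
    d95 = float(np.percentile(dose[ctv.voxel_indices], 5.0))
    if d95 <= 0:
        raise ValueError("CTV receives no dose; cannot normalize")
    return x * (prescription / d95)


def dvh_curve(
    dose: np.ndarray, structure: Structure, dose_bins: np.ndarray
) -> np.ndarray:
    """Cumulative DVH: fraction of the structure receiving at least each bin dose.

    Non-increasing; 1 at dose 0 and 0 beyond the maximum structure dose.
    """
    if structure.size == 0:
        raise ValueError("empty structure")
    bins = np.asarray(dose_bins, dtype=float)
    if bins.size > 1 and np.any(np.diff(bins) <= 0):
        raise ValueError("dose bins must be strictly increasing")
    d = np.asarray(dose, dtype=float)[structure.voxel_indices]
    return np.array([np.mean(d >= b) for b in bins])


def default_objectives(case, oar_limit: float = 40.0) -> list[ObjectiveTerm]:
    """A clinically-shaped default prescription for synthetic cases: uniform
    target dose with a hot-spot DVH-max cap, DVH-max sparing on each OAR, and a
    small integral-dose term on the body."""
    terms = [
        ObjectiveTerm("L2", "CTV", 100.0, 100.0),
        ObjectiveTerm("DVH_max", "CTV", 50.0, 110.0, 0.05),
        ObjectiveTerm("DVH_min", "CTV", 50.0, 98.0, 0.98),
    ]
    for s in case.structures:
        if s.role == "oar":
            terms.append(ObjectiveTerm("DVH_max", s.name, 20.0, oar_limit, 0.05))
    terms.append(ObjectiveTerm("L2", "BODY", 0.5, 0.0))
    return terms
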