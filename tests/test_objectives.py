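"""DVH objective, ICR active sets, and plan-quality metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elopt import (
    ActiveSets,
    ObjectiveTerm,
    conformity_index,
    dvh_curve,
    evaluate_objective,
    normalize_plan,
    update_active_sets,
)
from elopt.cases import Structure, StructureSet, VoxelGrid


def _structset(n_voxels, **structs):
    grid = VoxelGrid((n_voxels, 1, 1))
    out = []
    for name, (idx, role) in structs.items():
        out.append(Structure(name, np.asarray(idx), role))
    return StructureSet(out, grid)


@pytest.fixture()
def two_voxel_set():
    return _structset(4, S=([0, 1], "target"), BODY=(np.arange(4), "body"))


def test_objective_hand_value(two_voxel_set):
    """One L2 term, omega=1, two voxels, level 100, dose (110, 90) -> 100."""
    terms = [ObjectiveTerm("L2", "S", 1.0, 100.0)]
    dose = np.array([110.0, 90.0, 0.0, 0.0])
    active = update_active_sets(dose, terms, two_voxel_set)
    assert evaluate_objective(dose, terms, active, two_voxel_set) == pytest.approx(100.0)


def test_objective_zero_cases(two_voxel_set):
    dose = np.array([100.0, 100.0, 0.0, 0.0])
    terms = [ObjectiveTerm("L2", "S", 1.0, 100.0)]
    active = update_active_sets(dose, terms, two_voxel_set)
    assert evaluate_objective(dose, terms, active, two_voxel_set) == 0.0
    zero_w = [ObjectiveTerm("L2", "S", 0.0, 50.0)]
    active = update_active_sets(dose, zero_w, two_voxel_set)
    assert evaluate_objective(dose, zero_w, active, two_voxel_set) == 0.0


def test_objective_rejects_out_of_range(two_voxel_set):
    terms = [ObjectiveTerm("L2", "S", 1.0, 100.0)]
    with pytest.raises(IndexError):
        evaluate_objective(np.zeros(2), terms, ActiveSets([np.array([3])]),
                           two_voxel_set)


def test_dvh_max_excuses_highest_violators():
    """Doses 1..10, limit 5, 20% allowed above: 9 and 10 are excused, the
    active set is exactly the voxels at doses {6, 7, 8}."""
    ss = _structset(10, S=(np.arange(10), "oar"))
    dose = np.arange(1.0, 11.0)
    terms = [ObjectiveTerm("DVH_max", "S", 1.0, 5.0, 0.2)]
    act = update_active_sets(dose, terms, ss)
    assert sorted(dose[act[0]]) == [6.0, 7.0, 8.0]


def test_dvh_max_no_violators_empty():
    ss = _structset(6, S=(np.arange(6), "oar"))
    terms = [ObjectiveTerm("DVH_max", "S", 1.0, 50.0, 0.1)]
    act = update_active_sets(np.full(6, 10.0), terms, ss)
    assert len(act[0]) == 0


def test_l2_always_full_structure():
    ss = _structset(8, S=(np.arange(3, 8), "oar"))
    terms = [ObjectiveTerm("L2", "S", 1.0, 0.0)]
    act = update_active_sets(np.random.default_rng(0).random(8), terms, ss)
    assert np.array_equal(act[0], np.arange(3, 8))


def _brute_force_active(dose, term, idx):
    """Independent enumeration of the stated selection rule."""
    d = dose[idx]
    n = len(idx)
    if term.kind == "DVH_max":
        allowed = int(np.floor(term.volume_fraction * n))
        ranked = sorted(range(n), key=lambda k: (-d[k], idx[k]))
        excused = set(ranked[:allowed])
        return sorted(idx[k] for k in range(n)
                      if d[k] > term.dose_level and k not in excused)
    allowed = int(np.floor((1 - term.volume_fraction) * n))
    ranked = sorted(range(n), key=lambda k: (d[k], idx[k]))
    excused = set(ranked[:allowed])
    return sorted(idx[k] for k in range(n)
                  if d[k] < term.dose_level and k not in excused)


@settings(max_examples=60, deadline=None)
@given(
    doses=st.lists(st.integers(0, 20), min_size=1, max_size=12),
    kind=st.sampled_from(["DVH_max", "DVH_min"]),
    level=st.integers(0, 20),
    frac=st.floats(0.0, 1.0),
)
def test_active_set_matches_bruteforce_oracle(doses, kind, level, frac):
    """For structures <= 12 voxels, the vectorized H matches exhaustive
    evaluation of the selection rule (including integer dose ties)."""
    n = len(doses)
    ss = _structset(n, S=(np.arange(n), "oar"))
    dose = np.asarray(doses, dtype=float)
    term = ObjectiveTerm(kind, "S", 1.0, float(level), frac)
    act = update_active_sets(dose, [term], ss)
    assert sorted(act[0].tolist()) == _brute_force_active(dose, term, np.arange(n))


def test_active_set_size_bound():
    rng = np.random.default_rng(3)
    ss = _structset(50, S=(np.arange(50), "oar"))
    dose = rng.uniform(0, 100, 50)
    for v in (0.0, 0.13, 0.5, 1.0):
        term = ObjectiveTerm("DVH_max", "S", 1.0, 30.0, v)
        act = update_active_sets(dose, [term], ss)
        assert len(act[0]) <= 50 - int(np.floor(v * 50))


def test_update_active_sets_idempotent_at_fixed_dose(small_case, small_terms):
    dose = small_case.influence.dose(np.ones(small_case.influence.n_spots))
    a1 = update_active_sets(dose, small_terms, small_case.structures)
    a2 = update_active_sets(dose, small_terms, small_case.structures)
    for s1, s2 in zip(a1.sets, a2.sets):
        assert np.array_equal(s1, s2)


# -- conformity index ---------------------------------------------------------


def test_ci_ideal_and_half():
    ss = _structset(10, CTV=(np.arange(5), "target"), BODY=(np.arange(10), "body"))
    dose = np.zeros(10)
    dose[:5] = 100.0
    assert conformity_index(dose, ss["CTV"], ss["BODY"], 100.0) == pytest.approx(1.0)
    dose[5:] = 100.0  # V100 = 2 * V_CTV
    assert conformity_index(dose, ss["CTV"], ss["BODY"], 100.0) == pytest.approx(0.5)


def test_ci_zero_when_no_coverage():
    ss = _structset(4, CTV=([0, 1], "target"), BODY=(np.arange(4), "body"))
    assert conformity_index(np.full(4, 50.0), ss["CTV"], ss["BODY"], 100.0) == 0.0


def test_ci_rejects_empty_ctv():
    grid = VoxelGrid((4, 1, 1))
    body = Structure("BODY", np.arange(4), "body")
    fake_ctv = Structure("CTV", np.arange(1), "target")
    object.__setattr__(fake_ctv, "voxel_indices", np.array([], dtype=np.int64))
    with pytest.raises(ValueError):
        conformity_index(np.zeros(4), fake_ctv, body, 100.0)


# -- normalization ------------------------------------------------------------


class _IdentityInfluence:
    def dose(self, x):
        return np.asarray(x, dtype=float)


def test_normalize_uniform_half_dose_doubles():
    ctv = Structure("CTV", np.arange(5), "target")
    x = np.full(5, 50.0)
    xn = normalize_plan(x, _IdentityInfluence(), ctv, 100.0)
    assert np.allclose(xn, 100.0)


def test_normalize_fixed_point():
    ctv = Structure("CTV", np.arange(5), "target")
    x = np.full(5, 100.0)
    assert np.allclose(normalize_plan(x, _IdentityInfluence(), ctv, 100.0), x)


def test_normalize_rejects_zero_dose():
    ctv = Structure("CTV", np.arange(3), "target")
    with pytest.raises(ValueError):
        normalize_plan(np.zeros(3), _IdentityInfluence(), ctv, 100.0)


def test_normalization_preserves_ci(small_case, small_terms):
    """CI is invariant under joint rescaling of dose and threshold."""
    infl = small_case.influence
    x = np.ones(infl.n_spots)
    ctv, body = small_case.structures.target, small_case.structures.body
    xn = normalize_plan(x, infl, ctv, 100.0)
    scale = xn[0] / x[0]
    ci_scaled = conformity_index(infl.dose(xn), ctv, body, 100.0)
    ci_raw = conformity_index(infl.dose(x), ctv, body, 100.0 / scale)
    assert ci_scaled == pytest.approx(ci_raw)


# -- DVH curves ---------------------------------------------------------------


def test_dvh_curve_values_and_monotonicity():
    s = Structure("S", np.arange(3), "oar")
    dose = np.array([0.0, 50.0, 100.0])
    bins = np.array([0.0, 25.0, 75.0, 101.0])
    curve = dvh_curve(dose, s, bins)
    assert curve[0] == 1.0
    assert curve[1] == pytest.approx(2.0 / 3.0)
    assert curve[-1] == 0.0
    assert np.all(np.diff(curve) <= 0)


def test_dvh_uniform_dose_step():
    s = Structure("S", np.arange(4), "oar")
    curve = dvh_curve(np.full(4, 60.0), s, np.array([0.0, 59.9, 60.0, 60.1]))
    assert curve.tolist() == [1.0, 1.0, 1.0, 0.0]


def test_dvh_rejects_empty_structure():
    s = Structure("S", np.arange(1), "oar")
    object.__setattr__(s, "voxel_indices", np.array([], dtype=np.int64))
    with pytest.raises(ValueError):
        dvh_curve(np.zeros(3), s, np.array([0.0, 1.0]))
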