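"""Mixed-integer plan optimization by iterative convex relaxation + ADMM.

The planning model couples continuous spot intensities x with a binary layer
selection s under a cardinality budget (sum s = NE) and a minimum-monitor-unit
(MMU) constraint on each delivered spot (x_j in {0} u [G_min, inf)).  The
outer loop refreshes the DVH active sets from the current dose (iterative
convex relaxation); the inner ADMM sweep alternates

    x-step : conjugate gradient on the normal equations of the active-row
             least-squares problem with the selection mask applied,
    s-step : layer-selection QUBO (exact / annealing / variational-quantum),
    z-step : closed-form proximal projection onto the MMU-feasible set,
    duals  : lambda1 += x - z (vector), lambda2 += sum(s) - NE (scalar).

The plain IMPT baseline is the same loop with s frozen at all-ones and the
cardinality machinery disabled.

Robust optimization stacks per-scenario rows weighted by sqrt(scenario
weight), so the fitted objective is the weighted sum of per-scenario DVH
objectives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .cases import Case, DoseInfluence, ScenarioSet, StructureSet
from .objectives import ActiveSets, ObjectiveTerm, evaluate_objective, update_active_sets
from .qubo import qubo_from_columns, solve_annealing, solve_exact, solve_vqa, VQA_MAX_N

__all__ = [
    "ADMMConfig",
    "PlanVariables",
    "ADMMState",
    "assemble_scaled_matrix",
    "layer_columns",
    "solve_x",
    "project_mmu",
    "update_duals",
    "run_impt",
    "run_qc",
    "robust_objective",
]


@dataclass
class ADMMConfig:
    """Optimizer configuration.

    mu1, mu2
        Augmented-Lagrangian weights for the x = z split and the cardinality
        penalty.  'auto' scales mu1 to 0.1x the squared spectral norm of the
        stacked matrix (power iteration) and mu2 to the mean squared column
        norm of the layer-contribution matrix B at the first s-step, making
        the defaults dimension-free across synthetic cases.
    g_min
        MMU threshold: delivered intensities are 0 or >= g_min.  The default
        is a small fraction of the typical optimized spot intensity (which is
        O(1) in the synthetic cases), so the floor binds only the weakest
        spots — the clinically realistic regime for a deliverability limit.
    """

    mu1: float | str = "auto"
    mu2: float | str = "auto"
    g_min: float = 0.2
    cg_tol: float = 1e-6
    cg_max_iter: int = 300
    admm_max_iter: int = 10
    icr_outer_iter: int = 20
    primal_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if v != "auto" and float(v) <= 0:
                raise ValueError(f"{name} must be positive or 'auto'")
        if self.g_min <= 0:
            raise ValueError("g_min must be positive")
        if not 0 < self.cg_tol < 1 or not 0 < self.primal_tol < 1:
            raise ValueError("tolerances must lie in (0, 1)")


@dataclass
class PlanVariables:
    """ADMM iterate: intensities x, layer selection s, MMU copy z, duals."""

    x: np.ndarray
    s: np.ndarray
    z: np.ndarray
    lambda1: np.ndarray
    lambda2: float = 0.0

    def __post_init__(self):
        n = self.x.size
        if self.z.size != n or self.lambda1.size != n:
            raise ValueError("x, z, lambda1 must share length")
        if not np.all(np.isin(self.s, (0.0, 1.0))):
            raise ValueError("s must be binary")


@dataclass
class ADMMState:
    iterate: PlanVariables
    objective_history: list = field(default_factory=list)
    primal_residuals: list = field(default_factory=list)
    active: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    mu1: float = 0.0
    mu2: float = 0.0


# ---------------------------------------------------------------------------
# assembly


def _as_scenarios(case_or_influence) -> ScenarioSet:
    obj = case_or_influence
    if isinstance(obj, Case):
        obj = obj.influence
    if isinstance(obj, ScenarioSet):
        return obj
    if isinstance(obj, DoseInfluence):
        return ScenarioSet([obj], np.array([1.0]), 0, ["nominal"])
    raise TypeError("expected a Case, DoseInfluence or ScenarioSet")


def _active_list(active) -> list:
    if isinstance(active, ActiveSets):
        return [active]
    return list(active)


def assemble_scaled_matrix(case, active, terms, s=None):
    """Stack the weighted active rows into (A_tilde, b).

    Each term contributes its active rows of D scaled by sqrt(w_s * omega /
    |Omega|) (w_s the scenario weight); b holds the correspondingly scaled
    dose levels.  When ``s`` is given, the columns of each layer i are
    multiplied by s(i).  Rejects when every active set is empty.
    """
    scen = _as_scenarios(case)
    actives = _active_list(active)
    if len(actives) != scen.n_scenarios:
        raise ValueError("need one ActiveSets per scenario")
    rows, rhs = [], []
    for infl, w, act in zip(scen.scenarios, scen.weights, actives):
        D = infl.stacked
        for term, idx in zip(terms, act.sets):
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0 or term.weight == 0.0:
                continue
            scale = np.sqrt(w * term.weight / idx.size)
            rows.append(D[idx] * scale)
            rhs.append(np.full(idx.size, scale * term.dose_level))
    if not rows:
        raise ValueError("all active sets empty: nothing to fit")
    A = sparse.vstack(rows, format="csr")
    b = np.concatenate(rhs)
    if s is not None:
        mask = expand_selection(np.asarray(s, dtype=float), scen.nominal.layer_slices(),
                                A.shape[1])
        A = A @ sparse.diags(mask)
    return A, b


def expand_selection(s: np.ndarray, slices: list, n: int) -> np.ndarray:
    """Per-spot mask from the per-layer selection vector."""
    m = np.empty(n)
    for si, sl in zip(s, slices):
        m[sl] = si
    return m


def layer_columns(A, x: np.ndarray, slices: list) -> np.ndarray:
    """B with column i = A_i x_i: the dose contribution of layer i at x."""
    B = np.empty((A.shape[0], len(slices)))
    for i, sl in enumerate(slices):
        xi = np.zeros(A.shape[1])
        xi[sl] = x[sl]
        B[:, i] = A @ xi
    return B


def _spectral_norm_sq(A, rng: np.random.Generator, n_iter: int = 30) -> float:
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 1.0
        v = w / lam
    return lam


# ---------------------------------------------------------------------------
# the three primal steps and the dual update


def solve_x(A, b, z, lambda1, mu1, cg_tol=1e-6, cg_max_iter=300, x0=None):
    """Minimize ||A x - b||^2 + mu1 ||x - z + lambda1||^2 by conjugate gradient
    on the (positive-definite) normal equations, using only products with A
    and A^T.  Returns (x, converged); on non-convergence the best iterate is
    returned with a warning.
    """
    n = A.shape[1]
    rhs = A.T @ b + mu1 * (z - lambda1)

    def mv(v):
        return A.T @ (A @ v) + mu1 * v

    op = LinearOperator((n, n), matvec=mv, dtype=float)
    x, info = cg(op, rhs, x0=x0, rtol=cg_tol, atol=0.0, maxiter=cg_max_iter)
    converged = info == 0
    if not converged:
        warnings.warn("CG did not reach tolerance; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    return x, converged


def project_mmu(v, g_min: float):
    """Closest point of {0} u [g_min, inf): 0 below g_min/2, g_min on
    [g_min/2, g_min), identity above.  The tie at exactly g_min/2 resolves to
    g_min (keeps the spot deliverable).
    """
    if g_min <= 0:
        raise ValueError("g_min must be positive")
    v = np.asarray(v, dtype=float)
    out = np.where(v < g_min / 2.0, 0.0, np.maximum(v, g_min))
    return out if out.ndim else float(out)


def update_duals(state: PlanVariables, ne: int) -> PlanVariables:
    """lambda1 += x - z; lambda2 += sum(s) - NE (in place; returns state)."""
    state.lambda1 = state.lambda1 + state.x - state.z
    state.lambda2 = float(state.lambda2 + state.s.sum() - ne)
    return state


# ---------------------------------------------------------------------------
# full solves

_QUBO_SOLVERS = ("exact", "anneal", "vqa")


def _solve_qubo(q, choice: str, seed: int):
    from .qubo import AnnealSchedule

    if choice == "vqa" and q.n > VQA_MAX_N:
        choice = "anneal"  # statevector infeasible at clinical layer counts
    if choice == "exact":
        return solve_exact(q)
    if choice == "anneal":
        # lighter schedule than the standalone default: the QUBO is re-solved
        # every ADMM sweep from a fresh restart pool, so per-sweep polish
        # matters less than throughput
        return solve_annealing(q, AnnealSchedule(n_sweeps=60), n_restarts=6,
                               seed=seed)
    if choice == "vqa":
        return solve_vqa(q, seed=seed)
    raise ValueError(f"unknown QUBO solver {choice!r}; choose from {_QUBO_SOLVERS}")


def robust_objective(x, case, terms, structures=None) -> float:
    """Weighted sum of per-scenario DVH objectives at intensities x, with the
    active sets refreshed from each scenario's dose."""
    scen = _as_scenarios(case)
    structures = structures if structures is not None else case.structures
    f = 0.0
    for infl, w in zip(scen.scenarios, scen.weights):
        d = infl.dose(x)
        act = update_active_sets(d, terms, structures)
        f += w * evaluate_objective(d, terms, act, structures)
    return f


def _repair_cardinality(s, B, b, ne):
    """Greedy add/remove of layers by smallest marginal change of ||Bs - b||^2
    until sum(s) == NE."""
    s = s.copy()
    r = B @ s - b
    col_sq = np.einsum("ij,ij->j", B, B)
    while s.sum() < ne:
        cand = np.flatnonzero(s == 0)
        gains = 2.0 * (B[:, cand].T @ r) + col_sq[cand]
        j = cand[int(np.argmin(gains))]
        s[j] = 1.0
        r = r + B[:, j]
    while s.sum() > ne:
        cand = np.flatnonzero(s == 1)
        gains = -2.0 * (B[:, cand].T @ r) + col_sq[cand]
        j = cand[int(np.argmin(gains))]
        s[j] = 0.0
        r = r - B[:, j]
    return s


def _run(case, terms, ne, config, qubo_choice, freeze_s, scenarios):
    scen = _as_scenarios(scenarios if scenarios is not None else case)
    structures: StructureSet = case.structures
    N = scen.nominal.n_layers
    n = scen.nominal.n_spots
    slices = scen.nominal.layer_slices()
    if not 1 <= ne <= N:
        raise ValueError(f"NE must lie in [1, {N}], got {ne}")
    rng = np.random.default_rng(config.seed)
    prescription = getattr(case, "prescription", 100.0)

    # initialization: uniform intensities scaled to the prescription
    D0 = scen.nominal.stacked
    ctv = structures.target
    d_unit = D0 @ np.ones(n)
    mean_ctv = float(d_unit[ctv.voxel_indices].mean())
    if mean_ctv <= 0:
        raise ValueError("target receives no dose from unit intensities")
    x = np.full(n, prescription / mean_ctv)
    s = np.ones(N)
    z = project_mmu(x, config.g_min)
    lam1 = np.zeros(n)
    lam2 = 0.0
    mu1 = None if config.mu1 == "auto" else float(config.mu1)
    mu2 = None if config.mu2 == "auto" else float(config.mu2)

    history, residuals, warns = [], [], []
    actives = None
    B = None
    for outer in range(config.icr_outer_iter):
        m = expand_selection(s, slices, n)
        actives = [
            update_active_sets(infl.dose(x * m), terms, structures)
            for infl in scen.scenarios
        ]
        A, b = assemble_scaled_matrix(scen, actives, terms)
        if mu1 is None:
            mu1 = 0.1 * _spectral_norm_sq(A, rng)

        for inner in range(config.admm_max_iter):
            mask = expand_selection(s, slices, n)
            A_masked = _MaskedOperator(A, mask)
            x, ok = solve_x(A_masked, b, z, lam1, mu1, config.cg_tol,
                            config.cg_max_iter, x0=x)
            if not ok:
                warns.append(f"CG tolerance not met (outer {outer}, inner {inner})")
            if not freeze_s:
                B = layer_columns(A, x, slices)
                if mu2 is None:
                    mu2 = float(np.mean(np.einsum("ij,ij->j", B, B))) or 1.0
                q = qubo_from_columns(B, b, mu2, ne, lam2)
                sol = _solve_qubo(q, qubo_choice, seed=int(rng.integers(2**31 - 1)))
                s = sol.s
                mask = expand_selection(s, slices, n)
            z = project_mmu(x * mask + lam1, config.g_min)
            lam1 = lam1 + x * mask - z
            if not freeze_s:
                lam2 = float(lam2 + s.sum() - ne)
        mask = expand_selection(s, slices, n)
        residuals.append(float(np.linalg.norm(x * mask - z)))
        x_proj = project_mmu(x * mask, config.g_min)
        history.append(robust_objective(x_proj, scen, terms, structures))

    if not freeze_s and int(s.sum()) != ne:
        if B is None:
            B = layer_columns(A, x, slices)
        s = _repair_cardinality(s, B, b, ne)
        warns.append("cardinality repaired at termination")
    if mu2 is None:
        mu2 = 0.0

    mask = expand_selection(s, slices, n)
    x_final = project_mmu(x * mask, config.g_min)
    f_final = robust_objective(x_final, scen, terms, structures)
    variables = PlanVariables(x_final, s, z, lam1, lam2)
    state = ADMMState(variables, history, residuals, actives, warns, mu1, mu2)
    return variables, f_final, state


class _MaskedOperator:
    """A_tilde = A diag(mask): matrix products without rebuilding A."""

    def __init__(self, A, mask):
        self._A = A
        self._mask = mask
        self.shape = A.shape
        self.T = _MaskedOperatorT(A, mask)

    def __matmul__(self, v):
        return self._A @ (self._mask * v)


class _MaskedOperatorT:
    def __init__(self, A, mask):
        self._A = A
        self._mask = mask
        self.shape = (A.shape[1], A.shape[0])

    def __matmul__(self, y):
        return self._mask * (self._A.T @ y)


def run_qc(case, terms, ne, config=None, qubo="exact", scenarios=None,
           freeze_s=False):
    """Solve the cardinality-constrained plan: returns (PlanVariables, f, state).

    The returned selection satisfies sum(s) = NE exactly (repaired at
    termination if the penalty has not pinned it), deselected layers carry
    zero intensity, and every delivered intensity respects the MMU threshold.
    """
    config = config or ADMMConfig()
    return _run(case, terms, ne, config, qubo, freeze_s, scenarios)


def run_impt(case, terms, config=None, scenarios=None):
    """Plain IMPT baseline (all layers active): returns (x, f, state)."""
    config = config or ADMMConfig()
    scen = _as_scenarios(scenarios if scenarios is not None else case)
    variables, f, state = _run(case, terms, scen.nominal.n_layers, config,
                               "exact", True, scenarios)
    return variables.x, f, state
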