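"""Layer-selection QUBO: construction and solvers.

The binary subproblem of the ADMM sweep is

    min_{s in {0,1}^N}  ||B s - b||^2 + mu2 (1^T s - NE + lambda2)^2

where column i of B is the active-row dose contribution A_i(Omega) x_i of
energy layer i at the current intensities.  Expanding gives the QUBO

    energy(s) = s^T Q s - 2 c^T s,      Q = B^T B + mu2 11^T,
    c = B^T b + mu2 (NE - lambda2) 1,   constant = ||b||^2 + mu2 (NE - lambda2)^2,

with energy(s) + constant equal to the original objective for every binary s.

Three solvers are provided: exact enumeration (the ground-truth oracle,
N <= 24), best-of-restarts single-flip Metropolis simulated annealing, and a
QAOA-style variational routine on a dense statevector (N <= 16): the QUBO is
mapped to a diagonal Ising cost Hamiltonian via s_i = (1 - sigma_i)/2, a
parameterized circuit alternates cost-phase and transverse-field mixer
unitaries, and a derivative-free classical optimizer (Nelder-Mead with seeded
multi-starts) minimizes the expected energy; the answer is the best basis
state among seeded measurement samples of the optimized state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "QUBOProblem",
    "QUBOSolution",
    "AnnealSchedule",
    "build_layer_qubo",
    "qubo_from_columns",
    "solve_exact",
    "solve_annealing",
    "solve_vqa",
    "qubo_to_ising",
    "ising_to_qubo",
]

EXACT_MAX_N = 24
VQA_MAX_N = 16


@dataclass
class QUBOProblem:
    """energy(s) = s^T Q s - 2 c^T s (Q symmetric); ``constant`` tracks the
    offset so energy(s) + constant recovers the original objective."""

    Q: np.ndarray
    c: np.ndarray
    constant: float = 0.0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError("Q must be square")
        if self.Q.shape[0] < 1:
            raise ValueError("empty QUBO")
        if self.c.shape != (self.Q.shape[0],):
            raise ValueError("c length must match Q")
        self.Q = 0.5 * (self.Q + self.Q.T)  # enforce the symmetric convention

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def energy(self, s: np.ndarray) -> float:
        s = np.asarray(s, dtype=float)
        return float(s @ self.Q @ s - 2.0 * self.c @ s)

    def all_energies(self) -> np.ndarray:
        """Energies of every basis state, indexed so bit k of the state index
        is s[k] with s[0] the most significant bit (index order is then
        lexicographic order of s)."""
        if self.n > EXACT_MAX_N:
            raise ValueError(f"enumeration limited to N <= {EXACT_MAX_N}")
        states = _all_states(self.n)
        return np.einsum("ij,jk,ik->i", states, self.Q, states) - 2.0 * states @ self.c


@dataclass
class QUBOSolution:
    s: np.ndarray
    energy: float
    solver: str
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AnnealSchedule:
    """Geometric Metropolis temperature schedule."""

    n_sweeps: int = 150
    t_start_rel: float = 2.0  # x typical |dE|
    t_end_rel: float = 1e-3


def _all_states(n: int) -> np.ndarray:
    idx = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(float)


def _bits_from_index(idx: int, n: int) -> np.ndarray:
    return np.array([(idx >> (n - 1 - k)) & 1 for k in range(n)], dtype=float)


def qubo_from_columns(
    B: np.ndarray, b: np.ndarray, mu2: float, ne: int, lambda2: float
) -> QUBOProblem:
    """QUBO for min_s ||B s - b||^2 + mu2 (1^T s - NE + lambda2)^2."""
    B = np.asarray(B, dtype=float)
    b = np.asarray(b, dtype=float)
    n = B.shape[1]
    if n == 0:
        raise ValueError("no layers: empty QUBO")
    ones = np.ones((n, n))
    Q = B.T @ B + mu2 * ones
    c = B.T @ b + mu2 * (ne - lambda2) * np.ones(n)
    constant = float(b @ b) + mu2 * (ne - lambda2) ** 2
    return QUBOProblem(Q, c, constant)


def build_layer_qubo(case, active, terms, x, mu2, ne, lambda2=0.0) -> QUBOProblem:
    """Assemble the layer-selection QUBO from a case at current intensities x.

    Column i of B is the stacked, weight-scaled dose contribution of layer i,
    A_i(Omega) x_i.  ``active`` is the ActiveSets (or per-scenario list) used
    to stack rows; see :func:`elopt.admm.assemble_scaled_matrix`.
    """
    from .admm import assemble_scaled_matrix, layer_columns

    A, b = assemble_scaled_matrix(case, active, terms, s=None)
    B = layer_columns(A, np.asarray(x, dtype=float), _layer_slices_of(case))
    return qubo_from_columns(B, b, mu2, ne, lambda2)


def _layer_slices_of(case):
    infl = case.influence if hasattr(case, "influence") else case
    if hasattr(infl, "nominal"):  # ScenarioSet
        infl = infl.nominal
    return infl.layer_slices()


def solve_exact(q: QUBOProblem) -> QUBOSolution:
    """Exhaustive enumeration (N <= 24); ties broken toward the
    lexicographically smallest s."""
    if q.n > EXACT_MAX_N:
        raise ValueError(
            f"N={q.n} exceeds the enumeration bound {EXACT_MAX_N}; "
            "use solve_annealing or solve_vqa"
        )
    best_e = np.inf
    best_idx = 0
    chunk = 1 << 18
    shifts = np.arange(q.n - 1, -1, -1)
    for start in range(0, 2**q.n, chunk):
        idx = np.arange(start, min(start + chunk, 2**q.n), dtype=np.int64)
        states = ((idx[:, None] >> shifts[None, :]) & 1).astype(float)
        e = np.einsum("ij,jk,ik->i", states, q.Q, states) - 2.0 * states @ q.c
        k = int(np.argmin(e))  # first occurrence = lexicographically smallest
        if e[k] < best_e:
            best_e = float(e[k])
            best_idx = int(idx[k])
    s = _bits_from_index(best_idx, q.n)
    return QUBOSolution(s, q.energy(s), "exact", {"n_states": 2**q.n})


def solve_annealing(
    q: QUBOProblem,
    schedule: AnnealSchedule | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> QUBOSolution:
    """Best-of-restarts single-flip Metropolis simulated annealing.

    Restarts run in parallel as rows of a state matrix; flip gains use the
    maintained field h = Q s, so each sweep is O(R N).  The returned energy is
    never worse than the all-zeros or all-ones states (both are candidate
    states by construction).
    """
    sched = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    n, R = q.n, max(1, int(n_restarts))
    diag = np.diag(q.Q).copy()

    S = (rng.random((R, n)) < 0.5).astype(float)
    # seed two restarts with the trivial states so they always compete
    S[0] = 0.0
    if R > 1:
        S[1] = 1.0
    h = S @ q.Q  # field: h[r, i] = sum_j Q_ij s_rj
    energies = np.einsum("ri,ri->r", S, h) - 2.0 * S @ q.c

    scale = max(np.abs(diag).max(), np.abs(q.c).max(), np.abs(q.Q).max(), 1e-12)
    t0 = sched.t_start_rel * scale
    t1 = sched.t_end_rel * scale
    n_steps = sched.n_sweeps * n
    temps = t0 * (t1 / t0) ** (np.arange(n_steps) / max(1, n_steps - 1))

    best_S = S.copy()
    best_E = energies.copy()
    rows = np.arange(R)
    flip_idx = rng.integers(0, n, size=(n_steps, R))
    accept_u = rng.random((n_steps, R))
    for step in range(n_steps):
        i = flip_idx[step]
        s_i = S[rows, i]
        # flipping s_i -> 1 - s_i changes the energy by
        # (1 - 2 s_i) * (Q_ii + 2 (h_i - Q_ii s_i) - 2 c_i)
        dE = (1.0 - 2.0 * s_i) * (
            diag[i] + 2.0 * (h[rows, i] - diag[i] * s_i) - 2.0 * q.c[i]
        )
        accept = (dE <= 0) | (accept_u[step] < np.exp(-np.clip(dE / temps[step], 0, 50)))
        if np.any(accept):
            r = rows[accept]
            ii = i[accept]
            delta = 1.0 - 2.0 * S[r, ii]
            S[r, ii] += delta
            h[r] += delta[:, None] * q.Q[ii]
            energies[r] += dE[accept]
            improved = energies[r] < best_E[r]
            if np.any(improved):
                ri = r[improved]
                best_E[ri] = energies[ri]
                best_S[ri] = S[ri]
    k = int(np.argmin(best_E))
    s = best_S[k]
    return QUBOSolution(
        s,
        q.energy(s),
        "anneal",
        {"restart_energies": best_E.copy(), "n_sweeps": sched.n_sweeps},
    )


# ---------------------------------------------------------------------------
# Ising mapping and QAOA statevector solver


def qubo_to_ising(q: QUBOProblem):
    """Map energy(s) under s_i = (1 - sigma_i)/2 to an Ising form

        E(sigma) = sum_{i<j} J_ij sigma_i sigma_j + sum_i h_i sigma_i + offset,

    with J symmetric and zero-diagonal (each pair counted once, i < j), such
    that E(1 - 2s) = energy(s) for every binary s.
    """
    Q, c = q.Q, q.c
    J = 0.5 * Q.copy()
    np.fill_diagonal(J, 0.0)
    h = c - 0.5 * Q.sum(axis=1)
    offset = 0.25 * (Q.sum() + np.trace(Q)) - float(c.sum())
    return J, h, float(offset)


def ising_to_qubo(J: np.ndarray, h: np.ndarray, offset: float) -> QUBOProblem:
    """Inverse of :func:`qubo_to_ising`: a QUBO whose energy(s) + constant
    equals the Ising energy at sigma = 1 - 2s."""
    J = 0.5 * (np.asarray(J, dtype=float) + np.asarray(J, dtype=float).T)
    h = np.asarray(h, dtype=float)
    Q = 2.0 * J
    np.fill_diagonal(Q, 0.0)
    c = J.sum(axis=1) + h
    constant = 0.5 * float(J.sum()) + float(h.sum()) + float(offset)
    return QUBOProblem(Q, c, constant=constant)


def ising_energy(sigma: np.ndarray, J: np.ndarray, h: np.ndarray, offset: float) -> float:
    sigma = np.asarray(sigma, dtype=float)
    return float(np.sum(np.triu(J, 1) * np.outer(sigma, sigma)) + h @ sigma + offset)


def _apply_mixer(psi: np.ndarray, beta: float, n: int) -> np.ndarray:
    """Apply exp(-i beta X) on every qubit of a statevector of shape (2,)*n."""
    cb, sb = np.cos(beta), -1j * np.sin(beta)
    for k in range(n):
        psi = np.moveaxis(psi, k, 0)
        psi = np.stack([cb * psi[0] + sb * psi[1], sb * psi[0] + cb * psi[1]])
        psi = np.moveaxis(psi, 0, k)
    return psi


def _qaoa_state(params: np.ndarray, phase: np.ndarray, n: int) -> np.ndarray:
    depth = params.size // 2
    psi = np.full(2**n, 2 ** (-n / 2), dtype=complex).reshape((2,) * n)
    flat_phase = phase.reshape((2,) * n)
    for p in range(depth):
        gamma, beta = params[2 * p], params[2 * p + 1]
        psi = psi * np.exp(-1j * gamma * flat_phase)
        psi = _apply_mixer(psi, beta, n)
    return psi.reshape(-1)


def solve_vqa(
    q: QUBOProblem,
    depth: int = 3,
    n_param_restarts: int = 5,
    n_shots: int = 1024,
    seed: int = 0,
) -> QUBOSolution:
    """QAOA-style variational solve on a dense statevector (N <= 16).

    The diagonal cost Hamiltonian holds the energy of every basis state
    (normalized to unit spectral scale for the phase separator); ``depth``
    alternations of cost and mixer unitaries are optimized by Nelder-Mead from
    ``n_param_restarts`` seeded random starts.  The final answer is the
    lowest-energy basis state among ``n_shots`` multinomial samples of the
    optimized state (plus its modal state); with ``n_shots=0`` the modal state
    alone is used.
    """
    if q.n > VQA_MAX_N:
        raise ValueError(
            f"N={q.n} exceeds the statevector bound {VQA_MAX_N}; use solve_annealing"
        )
    rng = np.random.default_rng(seed)
    n = q.n
    energies = q.all_energies()
    scale = max(np.abs(energies).max(), 1e-12)
    phase = energies / scale

    def expected(params: np.ndarray) -> float:
        psi = _qaoa_state(params, phase, n)
        return float(np.real(np.vdot(psi, phase * psi)))

    best_val = np.inf
    best_params = None
    converged = False
    for _ in range(max(1, int(n_param_restarts))):
        x0 = rng.uniform(0.0, np.pi, size=2 * depth)
        res = minimize(
            expected,
            x0,
            method="Nelder-Mead",
            options={"maxfev": 200 * depth, "xatol": 1e-4, "fatol": 1e-6},
        )
        if res.fun < best_val:
            best_val = float(res.fun)
            best_params = res.x
            converged = converged or bool(res.success)

    psi = _qaoa_state(best_params, phase, n)
    probs = np.abs(psi) ** 2
    probs = probs / probs.sum()
    candidates = {int(np.argmax(probs))}
    if n_shots > 0:
        samples = rng.choice(2**n, size=int(n_shots), p=probs)
        candidates.update(int(i) for i in np.unique(samples))
    cand = np.array(sorted(candidates))
    k = cand[int(np.argmin(energies[cand]))]
    s = _bits_from_index(int(k), n)
    diagnostics = {
        "expected_energy": best_val * scale,
        "params": best_params,
        "optimizer_converged": converged,
        "ground_probability": float(probs[int(np.argmin(energies))]),
    }
    if not converged:
        diagnostics["warning"] = "classical optimizer did not report convergence"
    return QUBOSolution(s, q.energy(s), "vqa", diagnostics)
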