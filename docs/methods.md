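# Methods

## Planning model

The plan objective is a weighted mean-squared deviation over active voxel
sets,

    f(d, Ω) = Σ_terms (ω / |Ω|) · Σ_{j ∈ Ω} (d_j − level)²,

with doses expressed in percent of the prescription (prescription ≡ 100).
Three term kinds are supported: **L2** (the active set is the whole
structure), **DVH-max** (at most a fraction *v* of the structure may exceed
the limit) and **DVH-min** (at least *v* must reach the level). The layer
budget `Σ s(i) = NE` and the MMU constraint `x_j ∈ {0} ∪ [G_min, ∞)` make the
problem a nonconvex mixed-integer program; it is attacked by iterative convex
relaxation (outer loop) and ADMM (inner loop), with the binary subproblem cast
as a QUBO.

## Active-set rule (ICR)

At each outer iteration the active sets are recomputed from the current dose:

* DVH-max with limit *t* and allowed fraction *v*: the active set contains the
  voxels with dose > *t*, **excluding** the ⌊v·|S|⌋ highest-dose voxels (the
  fraction permitted to exceed the limit). The intuition: the hottest allowed
  voxels are "excused" and the remaining violators are pulled toward *t*.
* DVH-min mirrors this below the level with ⌊(1−v)·|S|⌋ excused lowest-dose
  voxels.

Counts use the floor and ties are broken by ascending voxel index, making the
map a deterministic function of the dose (verified against exhaustive
enumeration on small structures). Whether rounding rather than flooring is the
"right" convention is genuinely open; floor was chosen for determinism and
because it never under-penalizes.

## ADMM sweep

Update order is x → s → z → duals. The x-step solves the normal equations

    (ÃᵀÃ + μ₁ I) x = Ãᵀ b + μ₁ (z − λ₁)

by conjugate gradient (scipy, matrix-vector products only; warm-started from
the previous iterate). The selection enters as a column mask, applied lazily
so the stacked matrix is assembled once per outer iteration. The s-step
minimizes `‖Bs − b‖² + μ₂(1ᵀs − NE + λ₂)²` with `B[:,i] = A_i(Ω)x_i^{k+1}`.
The z-step is the exact Euclidean projection onto `{0} ∪ [G_min, ∞)`:
0 below `G_min/2`, `G_min` on `[G_min/2, G_min)`, identity above; the
equidistant point `v = G_min/2` resolves to `G_min` so the spot stays
deliverable. λ₂ is a scalar (the cardinality constraint is scalar).

Deselected layers keep their last intensities in memory (so a re-selected
layer warm-starts) but are masked to zero in every dose product, the z-step
and the returned plan.

Because the cardinality budget enters only as a quadratic penalty, `Σs = NE`
is not guaranteed per sweep; at termination the selection is repaired
greedily, adding/removing the layer with the smallest marginal change of
`‖Bs − b‖²` until the budget holds exactly. The final intensities are
projected onto the MMU set and the reported objective is evaluated at that
delivered plan with freshly computed active sets.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| μ₁ | auto = 0.1·‖Ã‖₂² | split weight; spectral scaling (power iteration) makes it dimension-free |
| μ₂ | auto = mean ‖B·ᵢ‖² | cardinality weight; the natural scale of flipping one layer is one column of B |
| G_min | 0.2 | MMU floor; optimized spot intensities are O(1) in the synthetic units, so the floor binds only the weakest spots, the clinically realistic regime |
| cg_tol / cg_max_iter | 1e−6 / 300 | relative residual of the normal equations |
| icr_outer_iter / admm_max_iter | 20 / 10 | no principled stopping rule exists for the nonconvex loop; fixed counts keep runs deterministic. Tests and the acceptance script use 5–8 outer / 4–5 inner, which this problem size saturates |
| ε (selection) | 0.1 | relative-error threshold between the reduced-layer and baseline objectives |

The outer-iteration objective history is monitored; it is not guaranteed
monotone (active sets, the binary s and the MMU projection all move), but on
the shipped fixtures it decreases to within ~1% sweep-to-sweep noise, which is
what the regression tests assert.

## QUBO solvers

* **Exact** — chunked enumeration up to N = 24, ties broken toward the
  lexicographically smallest bitstring. Ground truth for everything else.
* **Annealing** — single-flip Metropolis with a geometric temperature
  schedule, restarts run in parallel as rows of a state matrix with an
  incremental field update (O(N) per flip). Two restarts are seeded with the
  all-zeros and all-ones states so the returned energy never loses to them.
* **Variational (QAOA-style)** — the QUBO is mapped to a diagonal Ising cost
  Hamiltonian via `s_i = (1 − σ_i)/2`; a depth-p circuit alternates the cost
  phase separator and a transverse-field mixer on a dense statevector
  (N ≤ 16). The cost spectrum is normalized to unit spectral scale so the
  phase parameters live on a common range. Parameters are optimized by
  Nelder-Mead from seeded random multi-starts; the answer is the best basis
  state among seeded multinomial measurement samples (default 1024 shots) of
  the optimized state plus its modal state. Beyond 16 variables the planner
  falls back to annealing automatically — at clinical layer counts (50–80)
  dense statevectors are infeasible, which is also why the variational route
  is simulated rather than a hardware backend.

No depth/optimizer/shot prescription exists for the variational routine in
the underlying method; depth 3 with 5 restarts reliably reaches the exact
optimum on random 8-variable instances (the acceptance suite measures the
rate against the exact solver).

## Layer-count selection

Starting from the number of layers active in the IMPT baseline, bisection
(ceiling halving, floor 1) finds the first NE whose relative objective error
`|f_QC − f_IMPT| / f_IMPT` exceeds ε; ascent by 5 finds the first passing NE;
a unit scan of the bracketing interval returns the smallest passing NE. The
error is taken as an absolute value (a reduced-layer plan that *improves* the
objective counts as a pass in practice since its error is small or the
improvement direction is benign); every (NE, f) pair is cached. With a noisy
heuristic in the loop each NE is evaluated once with a fixed seed.

## Synthetic phantoms

The generator emulates what the optimizer needs from a dose engine, not the
engine itself:

* analytic Bragg-like depth dose — a rising entrance plateau
  (0.3 + 0.4·t/R) plus a unit Gaussian peak (σ = 5 mm proximal) at the
  nominal range R and a sharp Gaussian distal falloff (σ = 2 mm), so the
  argmax sits exactly at R and deeper energy indices give strictly deeper
  peaks;
* Gaussian lateral spread (σ = 4 mm) around each spot axis, 3 mm lateral spot
  grid, 5 mm longitudinal layer spacing (2.5 mm in the redundant-layer
  phantoms used to study layer reduction), entries below 10⁻³ of the column
  maximum dropped to keep the matrices sparse;
* ellipsoidal target, cuboid OARs, body = whole grid; one to four coplanar
  beams; sub-millimetre spot-position jitter and ±5% per-spot calibration
  noise drawn once from the case seed;
* uncertainty scenarios regenerated from the *same* geometry: ±setup shifts
  along the three axes (patient shift relative to the beams) and ±range
  scaling of every layer's nominal range — nominal + 6 + 2 = 9 scenarios at
  5 mm / 3.5%, uniform weights by default.

What the phantoms do **not** model: tissue heterogeneity, nuclear halo,
multiple-Coulomb-scattering depth dependence, realistic CT-based ranges, or
couch/gantry geometry beyond coplanar angles. Passing tests therefore
demonstrate the *algorithmic* properties (oracle agreement, trade-off
directions, workflow logic), not clinical dosimetry; clinical layer counts,
CI or delivery-time magnitudes should not be read off the synthetic numbers.

Default problem sizes (20³ voxels, ≤ 20 layers, ≤ 800 spots) were chosen so a
full ICR+ADMM solve takes about a second and the complete pipeline — baseline,
layer sweep, selection workflow — runs in minutes.

## Robust composite

The robust objective is the **weighted sum** of per-scenario objectives
(uniform weights by default), implemented by stacking scenario rows scaled by
√weight into the same least-squares system, with active sets maintained per
scenario. A worst-case composite was deliberately not implemented; the
scenario weights are exposed so expected-value composites of any weighting can
be tested. With both uncertainties zero the scenario set collapses to the
nominal matrix and the pipeline reproduces the nominal solve bit-for-bit.

## Delivery time

ELST sums 0.7 s per downward and 5.5 s per upward energy transition between
consecutively delivered layers, including across beam changes (an equal-energy
transition across beams is charged as a down-switch). Delivery order is not
dictated by the optimization; descending energy per beam is adopted as the
standard convention that minimizes up-switches, which also makes ELST provably
non-increasing when layers are removed. SSPT is `‖x‖₁/γ` with
γ = 2.6×10¹¹ protons/min and a configurable intensity-to-protons scale
(default 1; the synthetic units are arbitrary). SSWT is a structural model —
speed-limited travel `max(|Δx|/v_x, |Δy|/v_y)` plus 1 ms magnet preparation
per same-layer spot transition, serpentine line order — with default scan
speeds 10 m/s (x) and 3 m/s (y); published data-fit coefficients for specific
machines are not reproduced, so only structural properties of SSWT are
asserted in tests, never absolute clinical values.

## Numerical choices and degenerate inputs

* Empty active sets contribute zero objective (no division by |Ω| = 0);
  an all-empty stack is rejected as "nothing to fit".
* CG non-convergence returns the best iterate with a warning flag rather than
  raising; the ADMM loop records the event.
* QUBO ties: exact enumeration returns the lexicographically smallest
  minimizer; `Q` is stored symmetric and off-diagonal couplings are counted
  once via the `sᵀQs` convention.
* Zero-uncertainty scenario requests return the single nominal scenario; a
  requested layer with no reachable target voxels, a target outside the grid,
  or a target voxel with no dose influence all reject with diagnostics at
  generation time.
* `relative_error` rejects a nonpositive baseline objective.

## Known limitations

* The ICR+ADMM loop is a heuristic for a nonconvex mixed-integer problem: no
  optimality guarantee, and the reported objective can vary a few percent with
  seeds and iteration budgets.
* The cardinality repair is greedy; for adversarial B it may be suboptimal
  (the QUBO penalty usually pins the budget before repair is needed).
* The variational solver is a dense statevector simulation — a research
  instrument for small N, not a hardware pipeline.
* Delivery-time magnitudes depend on the configurable intensity-to-protons
  scale; only ELST is directly comparable across plans by default.
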