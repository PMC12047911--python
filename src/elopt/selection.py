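"""Practical selection of the number of active energy layers NE.

The workflow mirrors how a planner would tune NE against the full-layer IMPT
baseline: bisection halves NE from the baseline's active-layer count until the
relative objective error exceeds a threshold epsilon (the lower bound), then
NE ascends in increments of 5 until the error falls back under epsilon, and a
unit-step scan of the bracketing interval returns the smallest NE that meets
the threshold.  Every evaluated (NE, f) pair is cached so no NE is solved
twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .admm import ADMMConfig, run_impt, run_qc

__all__ = [
    "NESelectionConfig",
    "NESelectionResult",
    "relative_error",
    "bisect_lower_bound",
    "ascend_and_fine_tune",
    "find_lower_bound",
    "select_ne",
]


@dataclass
class NESelectionConfig:
    """epsilon: relative-error threshold (default 0.1); increment: ascent step
    (default 5); ne_floor: smallest NE the bisection may return."""

    epsilon: float = 0.1
    increment: int = 5
    ne_floor: int = 1

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.increment < 1 or self.ne_floor < 1:
            raise ValueError("increment and ne_floor must be >= 1")


@dataclass
class NESelectionResult:
    ne: int
    plan: object
    f: float
    f_impt: float
    trace: list = field(default_factory=list)  # (stage, NE, f, error)
    cache: dict = field(default_factory=dict)
    warning: str | None = None


def relative_error(f_qc: float, f_impt: float) -> float:
    """|f_qc - f_impt| / f_impt (absolute relative deviation from baseline)."""
    if f_impt <= 0:
        raise ValueError("degenerate IMPT baseline objective (f_impt <= 0)")
    return abs(f_qc - f_impt) / f_impt


# ---------------------------------------------------------------------------
# pure workflow kernels (testable against analytic mock error functions)


def bisect_lower_bound(error_fn, n_start: int, config: NESelectionConfig,
                       trace: list | None = None) -> int:
    """Halve NE (ceiling) from ``n_start`` until the relative error first
    exceeds epsilon; return that NE, or ``ne_floor`` if never exceeded."""
    trace = trace if trace is not None else []
    ne = int(n_start)
    if ne <= config.ne_floor:
        return config.ne_floor
    while ne > config.ne_floor:
        ne = max(config.ne_floor, math.ceil(ne / 2))
        err = error_fn(ne)
        trace.append(("bisect", ne, err))
        if err > config.epsilon:
            return ne
        if ne == config.ne_floor:
            break
    return config.ne_floor


def ascend_and_fine_tune(error_fn, ne_low: int, ne_max: int,
                         config: NESelectionConfig,
                         trace: list | None = None) -> tuple[int, bool]:
    """From ``ne_low``, ascend by ``increment`` until the error meets epsilon,
    then scan the bracketing interval (last failing NE, first passing NE] by
    unit steps; returns (smallest passing NE, ok).  If no NE <= ne_max passes,
    returns (ne_max, False)."""
    trace = trace if trace is not None else []
    ne = int(ne_low)
    err = error_fn(ne)
    trace.append(("ascend", ne, err))
    if err <= config.epsilon:
        return ne, True
    last_fail = ne
    while ne < ne_max:
        ne = min(ne + config.increment, ne_max)
        err = error_fn(ne)
        trace.append(("ascend", ne, err))
        if err <= config.epsilon:
            break
        last_fail = ne
    else:
        return ne_max, False
    first_pass = ne
    for cand in range(last_fail + 1, first_pass):
        err = error_fn(cand)
        trace.append(("fine", cand, err))
        if err <= config.epsilon:
            return cand, True
    return first_pass, True


# ---------------------------------------------------------------------------
# case-level wrappers


def _make_evaluator(case, terms, opt_config, qubo, scenarios, cache):
    def evaluate(ne: int):
        if ne not in cache:
            plan, f, _ = run_qc(case, terms, ne, opt_config, qubo=qubo,
                                scenarios=scenarios)
            cache[ne] = (f, plan)
        return cache[ne]

    return evaluate


def _baseline(case, terms, opt_config, scenarios):
    x, f_impt, state = run_impt(case, terms, opt_config, scenarios=scenarios)
    slices = (scenarios.nominal if scenarios is not None else case.influence
              ).layer_slices()
    n_start = int(sum(1 for sl in slices if np.any(x[sl] > 0)))
    return x, f_impt, max(1, n_start)


def find_lower_bound(case, terms, config=None, opt_config=None, qubo="exact",
                     scenarios=None) -> int:
    """Bisection lower bound for NE against the IMPT baseline of the case."""
    config = config or NESelectionConfig()
    opt_config = opt_config or ADMMConfig()
    _, f_impt, n_start = _baseline(case, terms, opt_config, scenarios)
    cache: dict = {}
    evaluate = _make_evaluator(case, terms, opt_config, qubo, scenarios, cache)
    return bisect_lower_bound(
        lambda ne: relative_error(evaluate(ne)[0], f_impt), n_start, config
    )


def select_ne(case, terms, config=None, opt_config=None, qubo="exact",
              scenarios=None) -> NESelectionResult:
    """Full NE-selection workflow; returns the chosen NE and its plan.

    The returned NE satisfies relative_error <= epsilon unless no NE up to the
    total layer count does, in which case the full count is returned with a
    warning recorded on the result.
    """
    config = config or NESelectionConfig()
    opt_config = opt_config or ADMMConfig()
    _, f_impt, n_start = _baseline(case, terms, opt_config, scenarios)
    n_total = (scenarios.nominal if scenarios is not None else case.influence
               ).n_layers
    cache: dict = {}
    evaluate = _make_evaluator(case, terms, opt_config, qubo, scenarios, cache)
    trace: list = []

    def err(ne: int) -> float:
        return relative_error(evaluate(ne)[0], f_impt)

    ne_low = bisect_lower_bound(err, n_start, config, trace)
    ne, ok = ascend_and_fine_tune(err, ne_low, n_total, config, trace)
    f, plan = evaluate(ne)
    warning = None if ok else (
        f"no NE <= {n_total} met epsilon={config.epsilon}; returning NE={ne}"
    )
    return NESelectionResult(ne, plan, f, f_impt, trace, cache, warning)
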