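"""Model / Results front end.

:class:`TreatmentPlanModel` bundles a case (optionally with uncertainty
scenarios) and a DVH prescription; ``fit()`` runs the plain IMPT solve,
``fit(ne=...)`` the cardinality-constrained solve, and ``select_layers()`` the
practical NE-selection workflow.  :class:`PlanResults` carries the optimized
intensities, layer selection, objective history and diagnostics, and exposes
the plan-quality metrics and delivery-time breakdown behind ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .admm import ADMMConfig, run_impt, run_qc
from .cases import Case, ScenarioSet
from .delivery import DeliveryTimeConfig, total_delivery_time
from .objectives import (
    conformity_index,
    default_objectives,
    dvh_curve,
    normalize_plan,
)
from .selection import NESelectionConfig, select_ne

__all__ = ["TreatmentPlanModel", "PlanResults"]


class TreatmentPlanModel:
    """Inverse-planning model for a (synthetic) PBS case.

    Parameters
    ----------
    case : Case
        Phantom geometry, spot layout and dose-influence matrices.
    objectives : list of ObjectiveTerm, optional
        DVH prescription; defaults to :func:`default_objectives`.
    scenarios : ScenarioSet, optional
        Setup/range uncertainty scenarios for robust optimization.
    config : ADMMConfig, optional
        Optimizer settings.
    """

    def __init__(self, case: Case, objectives=None, scenarios: ScenarioSet | None = None,
                 config: ADMMConfig | None = None):
        self.case = case
        self.objectives = objectives if objectives is not None else default_objectives(case)
        self.scenarios = scenarios
        self.config = config or ADMMConfig()

    def fit(self, ne: int | None = None, qubo: str = "exact",
            freeze_s: bool = False) -> "PlanResults":
        """Optimize the plan.

        ``ne=None`` runs the IMPT baseline (all layers); otherwise the
        mixed-integer solve with exactly ``ne`` active layers, the layer
        QUBO handled by the requested solver ('exact', 'anneal' or 'vqa').
        """
        if ne is None:
            x, f, state = run_impt(self.case, self.objectives, self.config,
                                   scenarios=self.scenarios)
            variables = state.iterate
            mode = "impt"
        else:
            variables, f, state = run_qc(self.case, self.objectives, ne,
                                         self.config, qubo=qubo,
                                         scenarios=self.scenarios,
                                         freeze_s=freeze_s)
            mode = "qc"
        return PlanResults(self, variables, f, state, mode, ne, qubo)

    def select_layers(self, selection_config: NESelectionConfig | None = None,
                      qubo: str = "exact"):
        """Run the practical NE-selection workflow (bisection, +5 ascent,
        unit fine-tune); returns the NESelectionResult, whose ``plan`` is the
        raw iterate of the chosen NE."""
        return select_ne(self.case, self.objectives,
                         selection_config or NESelectionConfig(),
                         self.config, qubo=qubo, scenarios=self.scenarios)


class PlanResults:
    """Fitted plan with diagnostics and plan-quality metrics.

    Doses are in percent of the prescription; metrics are computed on the
    nominal scenario after D95% = 100% renormalization (matching how plans
    are reported clinically).
    """

    def __init__(self, model, variables, objective, state, mode, ne, qubo):
        self.model = model
        self.variables = variables
        self.objective = float(objective)
        self.state = state
        self.mode = mode
        self.ne = ne
        self.qubo = qubo

    # -- basic accessors ----------------------------------------------------

    @property
    def x(self) -> np.ndarray:
        return self.variables.x

    @property
    def s(self) -> np.ndarray:
        return self.variables.s

    @property
    def n_energies(self) -> int:
        """Number of layers with nonzero delivered intensity."""
        slices = self.model.case.influence.layer_slices()
        return int(sum(1 for sl in slices if np.any(self.x[sl] > 0)))

    def dose(self, normalized: bool = False) -> np.ndarray:
        x = self.normalized_x() if normalized else self.x
        return self.model.case.influence.dose(x)

    def normalized_x(self) -> np.ndarray:
        """Intensities rescaled so CTV D95% = 100%."""
        case = self.model.case
        return normalize_plan(self.x, case.influence, case.structures.target,
                              case.prescription)

    # -- metrics ------------------------------------------------------------

    def conformity_index(self) -> float:
        case = self.model.case
        d = self.dose(normalized=True)
        return conformity_index(d, case.structures.target, case.structures.body,
                                case.prescription)

    def dvh(self, structure_name: str, dose_bins=None):
        case = self.model.case
        d = self.dose(normalized=True)
        if dose_bins is None:
            dose_bins = np.linspace(0.0, max(d.max(), case.prescription) * 1.05, 120)
        return dose_bins, dvh_curve(d, case.structures[structure_name], dose_bins)

    def delivery_time(self, config: DeliveryTimeConfig | None = None):
        return total_delivery_time(self.x, self.model.case.spots, config, self.s)

    def plot_dvh(self, structures=None, ax=None):
        """DVH curves for the (normalized) plan; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = structures or [s.name for s in self.model.case.structures]
        for name in names:
            bins, frac = self.dvh(name)
            ax.plot(bins, 100 * frac, label=name)
        ax.set_xlabel("dose (% of prescription)")
        ax.set_ylabel("volume (%)")
        ax.legend()
        return ax

    # -- summary ------------------------------------------------------------

    def summary(self, delivery_config: DeliveryTimeConfig | None = None) -> pd.Series:
        """Plan-quality row: Energy, f, CI, Dmax, per-structure mean doses and
        the delivery-time breakdown."""
        case = self.model.case
        d = self.dose(normalized=True)
        ctv = case.structures.target
        rows = {
            "Energy": self.n_energies,
            "f": self.objective,
            "CI": self.conformity_index(),
            "Dmax (%)": float(d[ctv.voxel_indices].max()),
        }
        for s in case.structures:
            if s.role != "target":
                rows[f"Dmean-{s.name} (%)"] = float(d[s.voxel_indices].mean())
        t = self.delivery_time(delivery_config)
        rows.update({"ELST (s)": t.elst_s, "SSPT (s)": t.sspt_s,
                     "SSWT (s)": t.sswt_s, "Total (s)": t.total_s})
        return pd.Series(rows, name=f"{self.mode}" + (f"-{self.ne}" if self.ne else ""))

    def __repr__(self):
        tag = self.mode if self.ne is None else f"{self.mode}(NE={self.ne})"
        return (f"<PlanResults {tag}: f={self.objective:.4g}, "
                f"energies={self.n_energies}>")
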