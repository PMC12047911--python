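"""Per-fraction delivery-time model: energy-layer switching time (ELST), spot
spill time (SSPT) and spot switching time (SSWT).

Machine constants follow the synchrotron-style model used throughout the
package: switching the beam energy *down* costs 0.7 s and *up* costs 5.5 s;
the spill time is the total delivered charge over the extraction rate
gamma = 2.6e11 protons/min; moving between spots costs the speed-limited
travel time plus a 1 ms magnet preparation.  Delivery order is beams in index
order, active layers in descending energy within each beam (standard practice
— it minimizes costly up-switches), spots in serpentine line order within a
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import SpotLayout

__all__ = [
    "DeliveryTimeConfig",
    "DeliveryTimeBreakdown",
    "delivery_sequence",
    "elst",
    "sspt",
    "sswt",
    "total_delivery_time",
]


@dataclass
class DeliveryTimeConfig:
    """Machine timing parameters (seconds, mm/s, protons/min)."""

    t_switch_down_s: float = 0.7
    t_switch_up_s: float = 5.5
    gamma_protons_per_min: float = 2.6e11
    t_magnet_prep_s: float = 0.001
    scan_speed_x_mm_per_s: float = 10_000.0
    scan_speed_y_mm_per_s: float = 3_000.0
    protons_per_intensity_unit: float = 1.0  # MU-to-protons scale

    def __post_init__(self):
        vals = (self.t_switch_down_s, self.t_switch_up_s,
                self.gamma_protons_per_min, self.t_magnet_prep_s,
                self.scan_speed_x_mm_per_s, self.scan_speed_y_mm_per_s,
                self.protons_per_intensity_unit)
        if any(v <= 0 for v in vals):
            raise ValueError("all machine parameters must be positive")


@dataclass
class DeliveryTimeBreakdown:
    elst_s: float
    sspt_s: float
    sswt_s: float

    @property
    def total_s(self) -> float:
        return self.elst_s + self.sspt_s + self.sswt_s

    def as_dict(self) -> dict:
        return {"elst_s": self.elst_s, "sspt_s": self.sspt_s,
                "sswt_s": self.sswt_s, "total_s": self.total_s}


def delivery_sequence(x: np.ndarray, layout: SpotLayout,
                      s: np.ndarray | None = None) -> list:
    """Ordered delivery steps (beam_id, layer_id, energy_index, spot_id, x_mm, y_mm).

    Beams in index order; within a beam, active layers (selected and carrying
    nonzero intensity) in descending energy; within a layer, spots with
    nonzero intensity in serpentine order: lines by ascending y, alternating x
    direction line by line.
    """
    x = np.asarray(x, dtype=float)
    spots = layout.spots
    layers = layout.layers
    active_layer = {}
    for lid, sl in zip(layers["layer_id"], layout.layer_slices()):
        selected = True if s is None else bool(s[int(lid)])
        active_layer[int(lid)] = selected and bool(np.any(x[sl] > 0))

    steps = []
    for beam_id in sorted(layers["beam_id"].unique()):
        blayers = layers[layers["beam_id"] == beam_id]
        blayers = blayers.sort_values("energy_index", ascending=False)
        for _, lay in blayers.iterrows():
            lid = int(lay["layer_id"])
            if not active_layer[lid]:
                continue
            sub = spots[(spots["layer_id"] == lid)]
            sub = sub[x[sub["spot_id"].to_numpy()] > 0]
            lines = sorted(sub["y_mm"].unique())
            reverse = False
            for y in lines:
                row = sub[sub["y_mm"] == y].sort_values("x_mm", ascending=not reverse)
                for _, sp in row.iterrows():
                    steps.append((int(beam_id), lid, int(lay["energy_index"]),
                                  int(sp["spot_id"]), float(sp["x_mm"]),
                                  float(sp["y_mm"])))
                reverse = not reverse
    if not steps:
        raise ValueError("no active spots: nothing to deliver")
    return steps


def elst(sequence: list, config: DeliveryTimeConfig) -> float:
    """Total energy-switching time: 0.7 s per downward and 5.5 s per upward
    energy transition between consecutive delivered layers (including across
    beam changes)."""
    t = 0.0
    prev = None
    for step in sequence:
        key = (step[0], step[1])  # (beam, layer)
        if prev is not None and key != (prev[0], prev[1]):
            if step[2] < prev[2]:
                t += config.t_switch_down_s
            elif step[2] > prev[2]:
                t += config.t_switch_up_s
            else:  # same energy in a different beam: re-switch counted as down
                t += config.t_switch_down_s
        if prev is None or key != (prev[0], prev[1]):
            prev = step
    return t


def sspt(x: np.ndarray, config: DeliveryTimeConfig) -> float:
    """Spot spill time: ||x||_1 / gamma, in seconds (gamma is per minute)."""
    x = np.asarray(x, dtype=float)
    protons = float(np.abs(x).sum()) * config.protons_per_intensity_unit
    return protons / config.gamma_protons_per_min * 60.0


def sswt(sequence: list, layout: SpotLayout, config: DeliveryTimeConfig) -> float:
    """Spot switching time: for consecutive spots within the same layer,
    max(|dx|/v_x, |dy|/v_y) + magnet preparation time; layer transitions are
    excluded (they are charged to ELST)."""
    t = 0.0
    for prev, cur in zip(sequence[:-1], sequence[1:]):
        if (prev[0], prev[1]) != (cur[0], cur[1]):
            continue
        dx = abs(cur[4] - prev[4])
        dy = abs(cur[5] - prev[5])
        travel = max(dx / config.scan_speed_x_mm_per_s,
                     dy / config.scan_speed_y_mm_per_s)
        t += travel + config.t_magnet_prep_s
    return t


def total_delivery_time(x: np.ndarray, layout: SpotLayout,
                        config: DeliveryTimeConfig | None = None,
                        s: np.ndarray | None = None) -> DeliveryTimeBreakdown:
    """Per-fraction breakdown; total is the exact sum of the three components."""
    config = config or DeliveryTimeConfig()
    seq = delivery_sequence(x, layout, s)
    return DeliveryTimeBreakdown(
        elst_s=elst(seq, config),
        sspt_s=sspt(x, config),
        sswt_s=sswt(seq, layout, config),
    )
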