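"""Shipped objective presets and clinical dose constraints.

The constraint set is the standard stage III lung-cancer table (cord
D_max < 45 Gy, total-lung V20 < 30%, contralateral-lung V5 < 50%,
MLD < 20 Gy, esophagus D_max < 105% of prescription, PTV D_min >= 90%,
body V110% confined to the PTV).  The optimization preset encodes that
table plus a PTV uniform-dose pair (min at prescription, max at 105%);
the exact per-structure optimizer levels are this package's defaults —
the clinical table constrains the *result*, not the optimizer input.
Target coverage carries the highest priority weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optimize import Objective

__all__ = ["PlanConstraints", "clinical_lung_preset", "check_constraints"]


@dataclass(frozen=True)
class PlanConstraints:
    """Acceptance thresholds checked on the final dose of every plan."""

    prescription_gy: float = 60.0
    ptv_dmin_fraction: float = 0.90        # PTV D_min >= 90% prescription
    body_hotspot_fraction: float = 1.10    # V110% confined within PTV
    cord_dmax_gy: float = 45.0
    lung_v20_pct: float = 30.0
    contralateral_v5_pct: float = 50.0
    mld_gy: float = 20.0
    esophagus_dmax_fraction: float = 1.05

    def __post_init__(self) -> None:
        vals = (
            self.prescription_gy, self.ptv_dmin_fraction,
            self.body_hotspot_fraction, self.cord_dmax_gy, self.lung_v20_pct,
            self.contralateral_v5_pct, self.mld_gy, self.esophagus_dmax_fraction,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all constraint thresholds must be positive")


def clinical_lung_preset(prescription_gy: float = 60.0) -> list[Objective]:
    """Default optimization objectives for the stage III lung sandbox."""
    p = prescription_gy
    return [
        Objective("ptv", "min_dose", p, None, 300.0),
        Objective("ptv", "max_dose", 1.05 * p, None, 200.0),
        Objective("spinal_cord", "max_dose", 42.0, None, 20.0),
        Objective("total_lung", "max_dvh", 20.0, 27.0, 5.0),
        Objective("total_lung", "mean_dose", 18.0, None, 4.0),
        Objective("contralateral_lung", "max_dvh", 5.0, 45.0, 2.0),
        Objective("esophagus", "max_dose", 1.02 * p, None, 8.0),
        Objective("heart", "max_dvh", 30.0, 40.0, 3.0),
        Objective("ring_1", "max_dose", 0.95 * p, None, 8.0),
        Objective("ring_2", "max_dose", 0.72 * p, None, 4.0),
        Objective("ring_3", "max_dose", 0.45 * p, None, 2.0),
        Objective("normal_tissue", "max_dose", 1.06 * p, None, 5.0),
    ]


def check_constraints(dose: np.ndarray, structures, constraints: PlanConstraints
                      ) -> pd.DataFrame:
    """Evaluate the clinical constraint table on a final dose grid.

    Returns a DataFrame with one row per constraint (value, limit,
    passed).  Failures are reported, never fatal: a plan that misses a
    constraint is flagged for review, mirroring clinical practice.
    """
    p = constraints.prescription_gy
    dose = np.asarray(dose, dtype=float)
    rows = []

    def add(name, value, limit, ok):
        rows.append({"constraint": name, "value": float(value),
                     "limit": float(limit), "passed": bool(ok)})

    ptv = structures["ptv"]
    dmin = dose[ptv].min()
    add("ptv_dmin_gy", dmin, constraints.ptv_dmin_fraction * p,
        dmin >= constraints.ptv_dmin_fraction * p)

    hot = (dose >= constraints.body_hotspot_fraction * p) & structures["body"]
    outside = int((hot & ~ptv).sum())
    add("body_v110_outside_ptv_voxels", outside, 0, outside == 0)

    cord_max = dose[structures["spinal_cord"]].max()
    add("cord_dmax_gy", cord_max, constraints.cord_dmax_gy,
        cord_max < constraints.cord_dmax_gy)

    lung = structures["total_lung"]
    v20 = 100.0 * (dose[lung] >= 20.0).mean()
    add("lung_v20_pct", v20, constraints.lung_v20_pct, v20 < constraints.lung_v20_pct)
    mld = dose[lung].mean()
    add("mld_gy", mld, constraints.mld_gy, mld < constraints.mld_gy)

    cl = structures["contralateral_lung"]
    v5 = 100.0 * (dose[cl] >= 5.0).mean()
    add("contralateral_v5_pct", v5, constraints.contralateral_v5_pct,
        v5 < constraints.contralateral_v5_pct)

    eso_max = dose[structures["esophagus"]].max()
    add("esophagus_dmax_gy", eso_max, constraints.esophagus_dmax_fraction * p,
        eso_max < constraints.esophagus_dmax_fraction * p)

    return pd.DataFrame(rows)
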