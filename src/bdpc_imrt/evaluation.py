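"""DVH computation and plan-quality metrics.

Implements the standard evaluation suite for thoracic IMRT plans:
cumulative dose-volume histograms, D_x% / V_x queries, the Paddick
conformity index, the ICRU-83 homogeneity index, mean lung dose, the
normal-tissue hot-spot volume, and the MU-derived peripheral-dose and
beam-on-time arithmetic.

Conventions: D_x% is the dose received by (at least) x% of a structure,
obtained by linear interpolation of the inverse cumulative curve; V_x is
the percent volume receiving >= x Gy.  The DVH bin width defaults to
0.05 Gy and the curve is exact at bin edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DVH",
    "PlanMetrics",
    "compute_dvh",
    "dvh_metrics",
    "paddick_ci",
    "homogeneity_index",
    "mu_derived",
    "nt_hotspot_volume",
    "compute_plan_metrics",
]

#: Peripheral dose measured 20 cm from the isocenter, cGy per MU.
PERIPHERAL_CGY_PER_MU = 2.44e-3
#: Standard delivery dose rate, MU per minute.
DOSE_RATE_MU_PER_MIN = 600.0


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    edges: np.ndarray            # dose bin edges, Gy
    cum_volume_pct: np.ndarray   # % of volume receiving >= edge
    voxel_count: int
    d_mean: float
    d_max: float
    d_min: float

    def d_at_volume(self, volume_pct: float) -> float:
        """D_x%: dose covering ``volume_pct`` percent of the structure
        (linear interpolation between bin edges)."""
        if not (0.0 <= volume_pct <= 100.0):
            raise ValueError("volume percentage must lie in [0, 100]")
        # cum is non-increasing in dose; reverse for np.interp
        return float(
            np.interp(volume_pct, self.cum_volume_pct[::-1], self.edges[::-1])
        )

    def v_at_dose(self, dose_gy: float) -> float:
        """V_x: percent volume receiving at least ``dose_gy``."""
        if dose_gy < 0:
            raise ValueError("dose query must be nonnegative")
        if dose_gy >= self.edges[-1]:
            return 0.0
        return float(np.interp(dose_gy, self.edges, self.cum_volume_pct))


def compute_dvh(
    dose: np.ndarray,
    mask: np.ndarray,
    bin_width_gy: float = 0.05,
    structure: str = "",
) -> DVH:
    """Cumulative DVH over the masked voxels, exact at bin edges."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    doses = np.asarray(dose, dtype=float)[mask]
    if doses.size == 0:
        raise ValueError(f"empty mask for structure {structure!r}")
    dmax = float(doses.max())
    edges = np.arange(0.0, dmax + 2.0 * bin_width_gy, bin_width_gy)
    srt = np.sort(doses)
    # % of voxels with dose >= edge
    cum = 100.0 * (doses.size - np.searchsorted(srt, edges, side="left")) / doses.size
    return DVH(
        structure=structure,
        edges=edges,
        cum_volume_pct=cum,
        voxel_count=int(doses.size),
        d_mean=float(doses.mean()),
        d_max=dmax,
        d_min=float(doses.min()),
    )


def dvh_metrics(
    dvh: DVH,
    d_queries_pct: list[float] = (),
    v_queries_gy: list[float] = (),
) -> dict[str, float]:
    """D_x% and V_x scalars from a DVH, plus mean/max dose."""
    out: dict[str, float] = {"d_mean": dvh.d_mean, "d_max": dvh.d_max}
    for x in d_queries_pct:
        out[f"d{x:g}pct"] = dvh.d_at_volume(x)
    for x in v_queries_gy:
        out[f"v{x:g}gy"] = dvh.v_at_dose(x)
    return out


def paddick_ci(
    dose: np.ndarray, ptv_mask: np.ndarray, prescription_gy: float
) -> float:
    """Paddick conformity index (TV_PIV)^2 / (TV x PIV).

    TV is the target volume, PIV the prescription isodose volume
    (voxels at or above the prescription), TV_PIV their overlap.  1 is
    ideal conformity; 0 means the prescription isodose misses the
    target entirely.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    tv = int(ptv_mask.sum())
    if tv == 0:
        raise ValueError("empty target volume")
    piv_mask = np.asarray(dose) >= prescription_gy
    piv = int(piv_mask.sum())
    if piv == 0:
        warnings.warn("prescription isodose volume is empty; CI defined as 0",
                      stacklevel=2)
        return 0.0
    tv_piv = int((piv_mask & ptv_mask).sum())
    return tv_piv**2 / (tv * piv)


def homogeneity_index(d2_gy: float, d98_gy: float, d50_gy: float) -> float:
    """ICRU-83 homogeneity index (D2% - D98%) / D50%; 0 is ideal."""
    if d50_gy <= 0:
        raise ValueError("D50% must be positive")
    if d2_gy < d98_gy:
        raise ValueError("D2% < D98% violates DVH ordering")
    return (d2_gy - d98_gy) / d50_gy


def mu_derived(
    mu_a: float,
    mu_b: float,
    peripheral_factor_cgy_per_mu: float = PERIPHERAL_CGY_PER_MU,
    dose_rate_mu_per_min: float = DOSE_RATE_MU_PER_MIN,
) -> tuple[float, float]:
    """Peripheral-dose (cGy) and beam-on-time (s) differences implied by
    an MU difference ``mu_a - mu_b`` at the given calibration."""
    if mu_a < 0 or mu_b < 0:
        raise ValueError("MU values must be nonnegative")
    delta = mu_a - mu_b
    return (
        delta * peripheral_factor_cgy_per_mu,
        delta / dose_rate_mu_per_min * 60.0,
    )


def nt_hotspot_volume(
    dose: np.ndarray,
    nt_mask: np.ndarray,
    prescription_gy: float,
    voxel_volume_cc: float,
) -> float:
    """Normal-tissue V_107%: absolute volume (cm^3) of normal-tissue
    voxels receiving >= 107% of the prescription."""
    nt_mask = np.asarray(nt_mask, dtype=bool)
    hot = np.asarray(dose)[nt_mask] >= 1.07 * prescription_gy
    return float(hot.sum()) * voxel_volume_cc


@dataclass
class PlanMetrics:
    """Scalar plan-quality metrics of one plan."""

    method: str
    d2: float
    d50: float
    d98: float
    ci: float
    hi: float
    mu_per_fraction: float
    mld_gy: float
    nt_v107_cc: float
    oar: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {
            "method": self.method,
            "d2_gy": self.d2,
            "d50_gy": self.d50,
            "d98_gy": self.d98,
            "ci": self.ci,
            "hi": self.hi,
            "mu_per_fraction": self.mu_per_fraction,
            "mld_gy": self.mld_gy,
            "nt_v107_cc": self.nt_v107_cc,
        }
        for organ, vals in self.oar.items():
            for k, v in vals.items():
                out[f"{organ}_{k}"] = v
        return out


#: OAR query plan: structure -> (D_x% list, V_x list, report max/mean)
_OAR_QUERIES = {
    "total_lung": {"v": (5.0, 10.0, 20.0, 30.0), "mean": True},
    "contralateral_lung": {"v": (5.0,), "mean": False},
    "esophagus": {"v": (35.0, 50.0, 60.0), "mean": True, "max": True},
    "heart": {"v": (30.0, 40.0), "mean": True},
    "spinal_cord": {"max": True},
}


def compute_plan_metrics(
    dose: np.ndarray,
    structures,
    prescription_gy: float,
    method: str = "",
    mu_per_fraction: float = float("nan"),
    bin_width_gy: float = 0.05,
) -> PlanMetrics:
    """Full Tables-style metric suite for a final (deliverable) dose grid."""
    ptv = structures["ptv"]
    dvh = compute_dvh(dose, ptv, bin_width_gy, "ptv")
    d2 = dvh.d_at_volume(2.0)
    d50 = dvh.d_at_volume(50.0)
    d98 = dvh.d_at_volume(98.0)
    oar: dict[str, dict[str, float]] = {}
    for organ, spec_q in _OAR_QUERIES.items():
        if organ not in structures or not structures[organ].any():
            continue
        odvh = compute_dvh(dose, structures[organ], bin_width_gy, organ)
        vals: dict[str, float] = {}
        for v in spec_q.get("v", ()):
            vals[f"v{v:g}_pct"] = odvh.v_at_dose(v)
        if spec_q.get("mean"):
            vals["dmean_gy"] = odvh.d_mean
        if spec_q.get("max"):
            vals["dmax_gy"] = odvh.d_max
        oar[organ] = vals
    mld = compute_dvh(dose, structures["total_lung"], bin_width_gy, "total_lung").d_mean
    return PlanMetrics(
        method=method,
        d2=d2,
        d50=d50,
        d98=d98,
        ci=paddick_ci(dose, ptv, prescription_gy),
        hi=homogeneity_index(d2, d98, d50),
        mu_per_fraction=mu_per_fraction,
        mld_gy=mld,
        nt_v107_cc=nt_hotspot_volume(
            dose, structures["normal_tissue"], prescription_gy,
            structures.voxel_volume_cc,
        ),
        oar=oar,
    )
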