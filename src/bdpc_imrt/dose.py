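"""Beamlet dose-influence matrices under two pencil-beam engines.

The sandbox deliberately carries *two* dose models:

* ``simplified`` — the fast model an optimizer would use: primary
  attenuation ``exp(-mu * depth)`` with the *geometric* depth (path
  length through the body, unit density everywhere) and a fixed lateral
  Gaussian kernel of width ``sigma0``.
* ``accurate`` — the heterogeneity-corrected model used for the final
  dose: attenuation along the *radiological* depth (density line
  integral), a lateral kernel that widens as local density falls
  (``sigma = sigma0 / rho``, clipped), and a deposition factor
  ``rho**gamma`` approximating the loss of lateral electronic
  equilibrium in low-density tissue.

Their systematic discrepancy inside and around lung tissue is the
optimization-convergence error the planning methods compensate for.  On
a uniform unit-density phantom the two engines coincide (up to
interpolation noise), so the error vanishes without heterogeneity.

Beams are coplanar parallel photon fields at configurable gantry
angles; each field is discretized into square beamlets.  The matrix
maps per-beamlet fluence weights to dose per voxel (Gy per unit
fluence); dose is linear in fluence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

__all__ = [
    "BeamGeometry",
    "EngineParams",
    "DoseInfluenceMatrix",
    "compute_dose_matrix",
    "dose_from_fluence",
    "LEFT_SIDED_ANGLES",
    "RIGHT_SIDED_ANGLES",
    "save_dose_matrix",
    "load_dose_matrix",
]

#: Standard six-field coplanar arrangements for left- and right-sided
#: stage III lung tumors.
LEFT_SIDED_ANGLES: tuple[float, ...] = (330.0, 20.0, 70.0, 120.0, 165.0, 210.0)
RIGHT_SIDED_ANGLES: tuple[float, ...] = (195.0, 240.0, 290.0, 340.0, 30.0, 150.0)


@dataclass(frozen=True)
class BeamGeometry:
    """Coplanar beam arrangement.

    Gantry angle 0 deg points from the anterior (+y); angles increase
    clockwise viewed from the feet, matching the IEC convention closely
    enough for a parallel-beam sandbox.  ``sad_mm`` is informational
    (parallel geometry is used).
    """

    gantry_angles_deg: tuple[float, ...] = LEFT_SIDED_ANGLES
    sad_mm: float = 1000.0
    beamlet_width_mm: float = 8.0
    energy: str = "6MV"

    def __post_init__(self) -> None:
        if len(self.gantry_angles_deg) < 1:
            raise ValueError("at least one beam is required")
        if any(not (0.0 <= a < 360.0) for a in self.gantry_angles_deg):
            raise ValueError("gantry angles must lie in [0, 360)")
        if self.beamlet_width_mm <= 0:
            raise ValueError("beamlet width must be positive")

    @classmethod
    def for_laterality(cls, laterality: str, **kw) -> "BeamGeometry":
        angles = LEFT_SIDED_ANGLES if laterality == "left" else RIGHT_SIDED_ANGLES
        return cls(gantry_angles_deg=angles, **kw)


@dataclass(frozen=True)
class EngineParams:
    """Pencil-beam physics parameters.

    mu_per_mm
        Linear attenuation coefficient, water-equivalent (~6 MV).
    sigma0_mm
        Lateral Gaussian kernel width in unit-density tissue.
    sigma_clip
        Upper clip of the density-widened kernel, in units of sigma0.
    deposition_exponent
        Accurate engine only: local dose deposition scales with
        ``rho**gamma``, a lumped model of lateral electronic
        disequilibrium in low-density tissue.  0 disables it.
    kernel_cutoff_sigma
        Lateral kernel truncation radius in units of the local sigma.
    sparsity_floor
        Matrix entries below this fraction of the beamlet maximum are
        dropped (bounds DVH discretization error).
    step_mm
        Ray-sampling step for depth line integrals.
    """

    mu_per_mm: float = 0.0025
    sigma0_mm: float = 4.0
    sigma_clip: float = 1.5
    deposition_exponent: float = 0.08
    kernel_cutoff_sigma: float = 3.5
    sparsity_floor: float = 1e-4
    step_mm: float = 2.0


@dataclass
class DoseInfluenceMatrix:
    """Sparse beamlet-to-voxel dose operator (Gy per unit fluence)."""

    matrix: sparse.csr_matrix       # (n_beamlets, n_voxels)
    engine: str                     # "simplified" | "accurate"
    geometry: BeamGeometry
    grid_shape: tuple[int, int, int]
    beam_id: np.ndarray             # (n_beamlets,) beam index
    beamlet_u: np.ndarray           # (n_beamlets,) lateral position, mm
    beamlet_z: np.ndarray           # (n_beamlets,) row position, mm
    beam_layout: list[tuple[int, int]] = field(default_factory=list)  # (nu, nz) per beam
    params: EngineParams = field(default_factory=EngineParams)

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[0]

    def dose(self, fluence: np.ndarray) -> np.ndarray:
        return dose_from_fluence(self, fluence)


def dose_from_fluence(matrix: DoseInfluenceMatrix, fluence: np.ndarray) -> np.ndarray:
    """Linear dose superposition: dose grid from per-beamlet weights."""
    fluence = np.asarray(fluence, dtype=float).ravel()
    if fluence.size != matrix.n_beamlets:
        raise ValueError(
            f"fluence length {fluence.size} != beamlet count {matrix.n_beamlets}"
        )
    if np.any(fluence < 0):
        raise ValueError("fluence weights must be nonnegative")
    if not np.all(np.isfinite(fluence)):
        raise ValueError("fluence weights must be finite")
    d = matrix.matrix.T @ fluence
    return d.reshape(matrix.grid_shape)


def _ray_depths(
    positions: np.ndarray,
    source_dir: np.ndarray,
    integrand: np.ndarray,
    spacing: np.ndarray,
    extent: np.ndarray,
    step: float,
) -> np.ndarray:
    """Line integral of ``integrand`` from each position back toward the
    source (trapezoid rule on fixed-step trilinear samples), in mm times
    integrand units."""
    diag = float(np.linalg.norm(extent))
    n_steps = int(np.ceil(diag / step)) + 1
    ks = np.arange(n_steps + 1, dtype=float)
    weights = np.ones(n_steps + 1)
    weights[0] = weights[-1] = 0.5

    out = np.empty(positions.shape[0])
    chunk = max(1, int(4_000_000 // (n_steps + 1)))
    for lo in range(0, positions.shape[0], chunk):
        pos = positions[lo : lo + chunk]                     # (m, 3)
        pts = pos[:, None, :] + ks[None, :, None] * step * source_dir  # (m, K, 3)
        idx = (pts + extent / 2.0) / spacing - 0.5
        samples = ndimage.map_coordinates(
            integrand,
            idx.reshape(-1, 3).T,
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(pos.shape[0], n_steps + 1)
        out[lo : lo + chunk] = step * (samples * weights).sum(axis=1)
    return out


def compute_dose_matrix(
    grid,
    body_mask: np.ndarray,
    geometry: BeamGeometry,
    engine: str = "accurate",
    params: EngineParams | None = None,
    aperture_mask: np.ndarray | None = None,
    aperture_margin_mm: float = 10.0,
) -> DoseInfluenceMatrix:
    """Compute the beamlet dose-influence matrix for one engine.

    ``aperture_mask`` (typically the PTV) restricts each field to the
    beamlets whose projection covers the mask plus
    ``aperture_margin_mm``; with ``None`` the field covers the whole
    body projection.
    """
    if params is None:
        params = EngineParams()
    if engine not in ("simplified", "accurate"):
        raise ValueError("engine must be 'simplified' or 'accurate'")
    density = np.asarray(grid.values, dtype=float)
    if not np.all(density > 0):
        raise ValueError("density grid must be strictly positive")
    body_mask = np.asarray(body_mask, dtype=bool)
    if body_mask.shape != density.shape:
        raise ValueError("body mask incongruent with density grid")

    shape = density.shape
    nz = shape[2]
    planar = nz == 1
    spacing = np.asarray(grid.spacing, dtype=float)
    extent = np.asarray(shape) * spacing
    w = geometry.beamlet_width_mm

    X, Y, Z = grid.voxel_centers()
    vox_flat = np.flatnonzero(body_mask.ravel())
    P = np.column_stack(
        [X.ravel()[vox_flat], Y.ravel()[vox_flat], Z.ravel()[vox_flat]]
    )
    rho_v = density.ravel()[vox_flat]

    if aperture_mask is not None:
        ap_flat = np.flatnonzero(np.asarray(aperture_mask, dtype=bool).ravel())
        if ap_flat.size == 0:
            raise ValueError("aperture mask is empty")
        AP = np.column_stack(
            [X.ravel()[ap_flat], Y.ravel()[ap_flat], Z.ravel()[ap_flat]]
        )
    else:
        AP = P

    if engine == "accurate":
        integrand = density
        sigma_v = np.clip(
            params.sigma0_mm / rho_v,
            0.5 * params.sigma0_mm,
            params.sigma_clip * params.sigma0_mm,
        )
        deposition = rho_v ** params.deposition_exponent
    else:
        integrand = body_mask.astype(float)
        sigma_v = np.full(rho_v.shape, params.sigma0_mm)
        deposition = np.ones_like(rho_v)

    mu = params.mu_per_mm
    cutoff = params.kernel_cutoff_sigma
    sigma_max = float(sigma_v.max()) if sigma_v.size else params.sigma0_mm

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    beam_ids: list[int] = []
    bl_u: list[float] = []
    bl_z: list[float] = []
    layout: list[tuple[int, int]] = []
    j_global = 0

    for b, ang in enumerate(geometry.gantry_angles_deg):
        g = np.deg2rad(ang)
        source_dir = np.array([np.sin(g), np.cos(g), 0.0])  # toward source
        e_u = np.array([np.cos(g), -np.sin(g), 0.0])

        depth = _ray_depths(P, source_dir, integrand, spacing, extent, params.step_mm)
        amp = np.exp(-mu * depth) * deposition

        u_v = P @ e_u
        z_v = P[:, 2]

        # Beamlet lattice covering the aperture projection plus margin.
        u_ap = AP @ e_u
        u_lo = u_ap.min() - aperture_margin_mm
        u_hi = u_ap.max() + aperture_margin_mm
        n_u = max(1, int(np.ceil((u_hi - u_lo) / w)))
        u_centers = u_lo + (np.arange(n_u) + 0.5) * w
        if planar:
            z_centers = np.array([float(Z.ravel()[0])])
        else:
            z_ap = AP[:, 2]
            z_lo = z_ap.min() - aperture_margin_mm
            z_hi = z_ap.max() + aperture_margin_mm
            n_zr = max(1, int(np.ceil((z_hi - z_lo) / w)))
            z_centers = z_lo + (np.arange(n_zr) + 0.5) * w
        layout.append((n_u, len(z_centers)))

        order = np.argsort(u_v)
        u_s = u_v[order]
        z_s = z_v[order]
        amp_s = amp[order]
        sig_s = sigma_v[order]
        idx_s = vox_flat[order]
        halfwidth = cutoff * sigma_max

        beam_has_dose = False
        for zc in z_centers:
            if not planar:
                zwin = np.abs(z_s - zc) <= halfwidth
            for uc in u_centers:
                lo = np.searchsorted(u_s, uc - halfwidth)
                hi = np.searchsorted(u_s, uc + halfwidth)
                sl = slice(lo, hi)
                du = u_s[sl] - uc
                sig = sig_s[sl]
                if planar:
                    r2 = du * du
                    keep = r2 <= (cutoff * sig) ** 2
                    if keep.any():
                        s = sig[keep]
                        val = (
                            amp_s[sl][keep]
                            * w
                            / (np.sqrt(2.0 * np.pi) * s)
                            * np.exp(-r2[keep] / (2.0 * s * s))
                        )
                    else:
                        val = np.empty(0)
                else:
                    dz = z_s[sl] - zc
                    r2 = du * du + dz * dz
                    keep = zwin[sl] & (r2 <= (cutoff * sig) ** 2)
                    if keep.any():
                        s = sig[keep]
                        val = (
                            amp_s[sl][keep]
                            * w * w
                            / (2.0 * np.pi * s * s)
                            * np.exp(-r2[keep] / (2.0 * s * s))
                        )
                    else:
                        val = np.empty(0)
                if val.size:
                    vmax = val.max()
                    strong = val >= params.sparsity_floor * vmax
                    col = idx_s[sl][keep][strong]
                    val = val[strong]
                    rows.append(np.full(val.size, j_global))
                    cols.append(col)
                    vals.append(val)
                    beam_has_dose = True
                beam_ids.append(b)
                bl_u.append(float(uc))
                bl_z.append(float(zc))
                j_global += 1
        if not beam_has_dose:
            warnings.warn(
                f"beam {b} at gantry {ang} deg deposits no dose in the body",
                stacklevel=2,
            )

    n_beamlets = j_global
    if rows:
        data = np.concatenate(vals)
        mat = sparse.csr_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_beamlets, int(np.prod(shape))),
        )
    else:
        mat = sparse.csr_matrix((n_beamlets, int(np.prod(shape))))

    return DoseInfluenceMatrix(
        matrix=mat,
        engine=engine,
        geometry=geometry,
        grid_shape=tuple(shape),
        beam_id=np.asarray(beam_ids),
        beamlet_u=np.asarray(bl_u),
        beamlet_z=np.asarray(bl_z),
        beam_layout=layout,
        params=params,
    )


def save_dose_matrix(path, dim: DoseInfluenceMatrix) -> None:
    """Persist a dose-influence matrix as a sparse-triplet container."""
    coo = dim.matrix.tocoo()
    np.savez_compressed(
        path,
        row=coo.row,
        col=coo.col,
        data=coo.data,
        shape=np.asarray(coo.shape),
        grid_shape=np.asarray(dim.grid_shape),
        engine=np.asarray(dim.engine),
        beam_id=dim.beam_id,
        beamlet_u=dim.beamlet_u,
        beamlet_z=dim.beamlet_z,
        beam_layout=np.asarray(dim.beam_layout),
        gantry_angles=np.asarray(dim.geometry.gantry_angles_deg),
        beamlet_width=np.asarray(dim.geometry.beamlet_width_mm),
    )


def load_dose_matrix(path) -> DoseInfluenceMatrix:
    d = np.load(path, allow_pickle=False)
    mat = sparse.csr_matrix(
        (d["data"], (d["row"], d["col"])), shape=tuple(d["shape"])
    )
    geom = BeamGeometry(
        gantry_angles_deg=tuple(float(a) for a in d["gantry_angles"]),
        beamlet_width_mm=float(d["beamlet_width"]),
    )
    return DoseInfluenceMatrix(
        matrix=mat,
        engine=str(d["engine"]),
        geometry=geom,
        grid_shape=tuple(int(n) for n in d["grid_shape"]),
        beam_id=d["beam_id"],
        beamlet_u=d["beamlet_u"],
        beamlet_z=d["beamlet_z"],
        beam_layout=[tuple(int(x) for x in row) for row in d["beam_layout"]],
    )
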