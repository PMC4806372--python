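"""Randomized synthetic thorax phantoms.

A phantom is a voxelized mass-density grid plus a set of named boolean
structure masks (PTV, lungs, esophagus, heart, spinal cord, body, rings,
normal tissue).  The geometry emulates a stage III lung-cancer planning
case: the planning target volume (PTV) straddles the boundary between the
ipsilateral lung and the mediastinum, so part of the target sits in
lung-density tissue and part in soft tissue.  That density contrast is
what drives the optimization-convergence error downstream; the phantoms
make every stage of the pipeline testable without any external imaging
data.

Coordinates are voxel-centered, 0-based, axis order (x, y, z) with x the
patient left-right axis, y anterior-posterior and z cranio-caudal.  World
coordinates are in mm, centered on the grid center (the isocenter).
Volumes are voxel count x voxel volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityGrid",
    "StructureSet",
    "PhantomConfig",
    "generate_thorax_phantom",
    "split_target_by_density",
    "make_rings",
    "save_phantom",
    "load_phantom",
]


@dataclass(frozen=True)
class DensityGrid:
    """Voxelized mass-density map (g/cm^3)."""

    values: np.ndarray          # (nx, ny, nz) densities, all > 0
    spacing: tuple[float, float, float]  # voxel edge lengths, mm

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-D (use nz=1 for planar mode)")
        if not np.all(self.values > 0):
            raise ValueError("all densities must be positive")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm, isocenter at origin) of voxel centers."""
        axes = [
            (np.arange(n) + 0.5) * s - n * s / 2.0
            for n, s in zip(self.shape, self.spacing)
        ]
        return np.meshgrid(*axes, indexing="ij")


class StructureSet:
    """Named boolean voxel masks sharing one grid.

    Invariants maintained by the generator: every mask is a subset of
    ``body``; ``ptv_soft`` and ``ptv_lung`` partition ``ptv``;
    ``normal_tissue`` is body minus PTV.
    """

    def __init__(
        self,
        masks: dict[str, np.ndarray],
        spacing: tuple[float, float, float],
        laterality: str = "left",
    ) -> None:
        shapes = {m.shape for m in masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid shape")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in masks.items()}
        self.spacing = tuple(float(s) for s in spacing)
        self.laterality = laterality

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cc(self, name: str) -> float:
        return int(self.masks[name].sum()) * self.voxel_volume_cc

    def indices(self, name: str) -> np.ndarray:
        """Flat voxel indices of a structure (C order)."""
        return np.flatnonzero(self.masks[name].ravel())


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for a synthetic thorax phantom.

    ``target_volume_range`` follows the cohort the sandbox emulates
    (mean PTV 275 cm^3, range 205-409 cm^3); in planar mode (nz == 1)
    the drawn volume only sets the equivalent-sphere radius of the
    target disk.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    target_volume_range: tuple[float, float] = (205.0, 409.0)  # cm^3
    lung_density_range: tuple[float, float] = (0.2, 0.35)      # g/cm^3
    soft_tissue_density: float = 1.0
    air_density: float = 1.2e-3
    laterality: str = "random"          # "left" | "right" | "random"
    exclude_ptv_from_lung: bool = True  # total lung = lungs minus PTV
    ring_distances_mm: tuple[float, ...] = (6.0, 14.0, 30.0)
    density_noise_sd: float = 0.0       # optional voxel noise, g/cm^3

    def __post_init__(self) -> None:
        lo, hi = self.target_volume_range
        if not (0 < lo <= hi):
            raise ValueError("invalid target volume range")
        llo, lhi = self.lung_density_range
        if not (0 < llo <= lhi):
            raise ValueError("invalid lung density range")
        if self.laterality not in ("left", "right", "random"):
            raise ValueError("laterality must be left, right or random")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    """Ellipsoid mask; a semi-axis of ``None``/inf means full extrusion."""
    q = np.zeros_like(X)
    for A, c, a in ((X, center[0], semi[0]), (Y, center[1], semi[1]), (Z, center[2], semi[2])):
        if a is not None and np.isfinite(a):
            q = q + ((A - c) / a) ** 2
    return q <= 1.0


def split_target_by_density(
    ptv_mask: np.ndarray, grid: DensityGrid, threshold: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the PTV into soft-tissue and lung-density components.

    Voxels with density below ``threshold`` (g/cm^3) go to ``ptv_lung``,
    the rest to ``ptv_soft``.  The two masks are disjoint and their union
    is the input mask.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("cannot split an empty PTV")
    lung = ptv_mask & (grid.values < threshold)
    soft = ptv_mask & ~lung
    return soft, lung


def make_rings(
    ptv_mask: np.ndarray,
    distances_mm: list[float],
    spacing: tuple[float, float, float],
    body_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Concentric shell structures around the PTV.

    ``distances_mm`` are strictly increasing outer radii; ring *i* holds
    voxels whose Euclidean distance to the PTV surface lies in
    (d_{i-1}, d_i].  Rings are mutually disjoint and exclude the PTV.
    """
    distances = list(distances_mm)
    if any(b <= a for a, b in zip(distances, distances[1:])) or any(
        d <= 0 for d in distances
    ):
        raise ValueError("ring distances must be positive and strictly increasing")
    if not distances:
        return {}
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    dt = ndimage.distance_transform_edt(~ptv_mask, sampling=spacing)
    rings: dict[str, np.ndarray] = {}
    prev = 0.0
    for i, d in enumerate(distances, start=1):
        ring = (dt > prev) & (dt <= d)
        if body_mask is not None:
            ring &= body_mask
        rings[f"ring_{i}"] = ring
        prev = d
    return rings


def generate_thorax_phantom(
    config: PhantomConfig,
) -> tuple[DensityGrid, StructureSet]:
    """Generate a randomized synthetic thorax phantom.

    Deterministic for a given config (the seed drives every random
    draw).  The PTV is a sphere (disk in planar mode) centered near the
    medial edge of the ipsilateral lung so it always straddles the
    lung / mediastinum density boundary; a soft-tissue tumor core keeps
    part of the target at unit density even deep inside the lung.

    Returns the density grid and the structure set.  Raises
    ``ValueError`` if the configured target volume cannot fit on the
    grid.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    sx, sy, sz = config.spacing
    planar = nz == 1

    X, Y, Z = DensityGrid(
        np.ones(config.shape), config.spacing
    ).voxel_centers()
    Lx, Ly, Lz = nx * sx, ny * sy, nz * sz

    laterality = config.laterality
    if laterality == "random":
        laterality = "left" if rng.random() < 0.5 else "right"
    sign = +1.0 if laterality == "left" else -1.0  # +x = patient left

    # Body: extruded ellipse filling most of the axial plane.
    body_ax, body_ay = 0.45 * Lx, 0.33 * Ly
    body = _ellipsoid(X, Y, Z, (0.0, 0.0, 0.0), (body_ax, body_ay, None))

    # Lungs: two ellipsoids, jittered per seed.
    lung_az = None if planar else 0.45 * Lz
    jx, jy = rng.uniform(-4.0, 4.0, size=2)
    lung_semi = (0.165 * Lx, 0.68 * body_ay, lung_az)
    c_ipsi = (sign * (0.215 * Lx + jx), -5.0 + jy, 0.0)
    c_contra = (-sign * (0.215 * Lx - jx), -5.0 - jy, 0.0)
    ipsi = _ellipsoid(X, Y, Z, c_ipsi, lung_semi) & body
    contra = _ellipsoid(X, Y, Z, c_contra, lung_semi) & body

    # Target volume and radius (equivalent sphere).
    vlo, vhi = config.target_volume_range
    margin = 0.03 * (vhi - vlo)
    volume_cc = rng.uniform(vlo + margin, vhi - margin)
    r = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm

    # PTV centered at the medial lung edge so the target straddles the
    # density boundary; large targets are pushed laterally so they never
    # reach the contralateral lung.
    medial_x = abs(c_ipsi[0]) - lung_semi[0]
    cx = medial_x + rng.uniform(-6.0, 6.0)
    contra_clearance = r - medial_x + 4.0
    if cx < contra_clearance:
        cx = contra_clearance + rng.uniform(0.0, 4.0)
    cx = sign * cx
    cy = c_ipsi[1] + rng.uniform(-8.0, 8.0)
    cz = 0.0 if planar else rng.uniform(-8.0, 8.0)
    ptv = _ellipsoid(X, Y, Z, (cx, cy, cz), (r, r, None if planar else r))
    if not bool((ptv & ~body).sum() == 0):
        raise ValueError(
            f"configured PTV volume {volume_cc:.0f} cm^3 does not fit inside "
            "the body on this grid; reduce the target volume or enlarge the grid"
        )
    if not ptv.any():
        raise ValueError("PTV empty on this grid; increase resolution")

    # Soft-tissue tumor core (gross tumor) inside the PTV.
    core = _ellipsoid(
        X, Y, Z, (cx, cy, cz), (0.45 * r, 0.45 * r, None if planar else 0.45 * r)
    )

    # OARs: simple parametric shapes placed per laterality.
    cord = _ellipsoid(X, Y, Z, (0.0, -0.79 * body_ay, 0.0), (5.0, 5.0, None)) & body
    eso = _ellipsoid(X, Y, Z, (0.0, -0.45 * body_ay, 0.0), (6.0, 6.0, None)) & body
    heart_az = None if planar else 0.35 * Lz
    heart = (
        _ellipsoid(
            X, Y, Z,
            (-0.07 * Lx, 0.25 * body_ay, -0.05 * Lz),
            (0.15 * Lx, 0.38 * body_ay, heart_az),
        )
        & body
    )

    # Density map.
    lung_density = rng.uniform(*config.lung_density_range)
    density = np.full(config.shape, config.air_density)
    density[body] = config.soft_tissue_density
    density[ipsi | contra] = lung_density
    density[core & body] = config.soft_tissue_density
    if config.density_noise_sd > 0:
        noise = rng.normal(0.0, config.density_noise_sd, size=config.shape)
        inside = body
        density[inside] = np.clip(
            density[inside] + noise[inside], 0.05, 1.2
        )
    grid = DensityGrid(density, config.spacing)

    ptv_soft, ptv_lung = split_target_by_density(ptv, grid, threshold=0.7)
    if not ptv_lung.any():
        warnings.warn(
            "generated PTV contains no lung-density voxels; the phantom "
            "will not exhibit an optimization-convergence error",
            stacklevel=2,
        )

    total_lung = ipsi | contra
    if config.exclude_ptv_from_lung:
        total_lung = total_lung & ~ptv

    masks = {
        "body": body,
        "ptv": ptv,
        "ptv_soft": ptv_soft,
        "ptv_lung": ptv_lung,
        "ipsilateral_lung": ipsi,
        "contralateral_lung": contra,
        "total_lung": total_lung,
        "spinal_cord": cord,
        "esophagus": eso,
        "heart": heart,
        "normal_tissue": body & ~ptv,
    }
    masks.update(make_rings(ptv, list(config.ring_distances_mm), config.spacing, body))
    return grid, StructureSet(masks, config.spacing, laterality=laterality)


def save_phantom(path, grid: DensityGrid, structures: StructureSet,
                 config: PhantomConfig | None = None) -> None:
    """Persist a phantom as a compressed array container plus, when a
    config is given, a JSON sidecar (``<path>.json``)."""
    arrays = {f"mask_{k}": v for k, v in structures.masks.items()}
    np.savez_compressed(
        path,
        density=grid.values,
        spacing=np.asarray(grid.spacing),
        laterality=np.asarray(structures.laterality),
        **arrays,
    )
    if config is not None:
        sidecar = str(path)
        if sidecar.endswith(".npz"):
            sidecar = sidecar[: -len(".npz")]
        with open(sidecar + ".json", "w") as fh:
            json.dump(asdict(config), fh, indent=2)


def load_phantom(path) -> tuple[DensityGrid, StructureSet]:
    data = np.load(path, allow_pickle=False)
    spacing = tuple(float(s) for s in data["spacing"])
    grid = DensityGrid(data["density"], spacing)
    masks = {
        k[len("mask_"):]: data[k] for k in data.files if k.startswith("mask_")
    }
    laterality = str(data["laterality"]) if "laterality" in data.files else "left"
    return grid, StructureSet(masks, spacing, laterality=laterality)
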