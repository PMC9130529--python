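"""Steady-state photon diffusion on a voxelized cube.

Solves  -div(D grad Phi) + mua Phi = q0  with a cell-centered 7-point
finite-volume stencil, harmonic-mean face diffusivities and a Robin
(partial-current) boundary condition.  The collimated beam striking the
cube face is represented, as usual in the diffusion approximation, by an
isotropic point source one transport mean free path 1/mu_s' inside the
face, snapped to the nearest voxel center.

Fluence is normalized to unit source power, so Phi carries 1/cm^2; every
downstream quantity of interest is a ratio, which makes the absolute
calibration irrelevant.

The assembled system is symmetric positive definite and is solved by
Jacobi-preconditioned conjugate gradients with a fixed iteration order,
so identical inputs give bit-identical fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import GeometryError, MediumGeometry, SolverOptions


class ConvergenceError(RuntimeError):
    """The iterative solver failed to reach the requested residual."""


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform cell-centered cubic grid.

    Cell (i, j, k) has its center at ((i + 1/2) h, (j + 1/2) h, (k + 1/2) h),
    indices 0-based.
    """

    cells_per_axis: int
    spacing_cm: float

    @property
    def side_cm(self) -> float:
        return self.cells_per_axis * self.spacing_cm

    def centers(self) -> np.ndarray:
        """1D array of cell-center coordinates along one axis [cm]."""
        return (np.arange(self.cells_per_axis) + 0.5) * self.spacing_cm

    def nearest_index(self, coord: float) -> int:
        i = int(round(coord / self.spacing_cm - 0.5))
        return min(max(i, 0), self.cells_per_axis - 1)


@dataclass(frozen=True)
class OpticalMedium:
    """Per-voxel optical properties on a grid."""

    grid: VoxelGrid
    mua: np.ndarray      # 1/cm
    musp: np.ndarray     # 1/cm
    d: np.ndarray        # diffusion coefficient, cm


@dataclass(frozen=True)
class FluenceField:
    """Converged fluence field with solver provenance."""

    grid: VoxelGrid
    phi: np.ndarray                       # 1/cm^2 per unit source power
    source_position_cm: tuple[float, float, float]
    source_voxel: tuple[int, int, int]
    iterations: int
    residual: float
    diagnostics: dict = field(default_factory=dict)


def absorber_mask(grid: VoxelGrid, geometry: MediumGeometry) -> np.ndarray:
    """Boolean mask of the absorber voxels.

    Membership uses half-open intervals [center - a/2, center + a/2) per
    axis so that grid-aligned absorber boundaries never double-count cells.
    """
    centers = grid.centers()
    half = geometry.absorber_side_cm / 2.0
    masks = []
    for axis in range(3):
        c = geometry.absorber_center_cm[axis]
        masks.append((centers >= c - half - 1e-12) & (centers < c + half - 1e-12))
    return (
        masks[0][:, None, None] & masks[1][None, :, None] & masks[2][None, None, :]
    )


def build_medium(
    geometry: MediumGeometry,
    musp_percm: float,
    d_convention: str = "mua_plus_musp",
) -> OpticalMedium:
    """Voxelize the geometry at one value of the reduced scattering coefficient."""
    if musp_percm <= 0:
        raise ValueError(f"musp must be positive, got {musp_percm}")
    ratio = geometry.absorber_side_cm / geometry.grid_spacing_cm
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"absorber side {geometry.absorber_side_cm} cm is not grid-aligned "
            f"at h={geometry.grid_spacing_cm} cm; snapping to voxel membership",
            stacklevel=2,
        )
    grid = VoxelGrid(geometry.cells_per_axis, geometry.grid_spacing_cm)
    n = grid.cells_per_axis
    mua = np.full((n, n, n), geometry.mua_background_percm)
    mua[absorber_mask(grid, geometry)] = geometry.mua_absorber_percm
    musp = np.full((n, n, n), musp_percm)
    if d_convention == "mua_plus_musp":
        d = 1.0 / (3.0 * (mua + musp))
    elif d_convention == "musp_only":
        d = 1.0 / (3.0 * musp)
    else:
        raise ValueError(f"unknown d_convention {d_convention!r}")
    return OpticalMedium(grid=grid, mua=mua, musp=musp, d=d)


def extrapolation_factor(n_rel: float) -> float:
    """Index-mismatch factor A = (1 + r_d)/(1 - r_d) for the Robin condition.

    Uses the Groenhuis polynomial fit for the internal diffuse reflectance
    r_d as a function of the relative refractive index.
    """
    rd = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + rd) / (1.0 - rd)


def _assemble(medium: OpticalMedium, options: SolverOptions):
    """Build the SPD system matrix (CSR) scaled by the cell volume h^3."""
    grid = medium.grid
    n = grid.cells_per_axis
    h = grid.spacing_cm
    N = n**3
    d = medium.d
    diag = (medium.mua * h**3).ravel().copy()

    idx = np.arange(N).reshape(n, n, n)
    rows, cols, vals = [], [], []

    for axis in range(3):
        d1 = np.moveaxis(d, axis, 0)[:-1]
        d2 = np.moveaxis(d, axis, 0)[1:]
        df = 2.0 * d1 * d2 / (d1 + d2)                 # harmonic mean at faces
        w = (df * h).ravel()
        i1 = np.moveaxis(idx, axis, 0)[:-1].ravel()
        i2 = np.moveaxis(idx, axis, 0)[1:].ravel()
        np.add.at(diag, i1, w)
        np.add.at(diag, i2, w)
        rows.append(i1); cols.append(i2); vals.append(-w)
        rows.append(i2); cols.append(i1); vals.append(-w)

    a_factor = 1.0 if options.boundary == "matched" else extrapolation_factor(options.n_rel)
    for axis in range(3):
        for side in (0, -1):
            d_face = np.moveaxis(d, axis, 0)[side].ravel()
            i_face = np.moveaxis(idx, axis, 0)[side].ravel()
            # outward partial current per unit area: Phi * 2D/(h + 4 A D)
            cb = h**2 * 2.0 * d_face / (h + 4.0 * a_factor * d_face)
            np.add.at(diag, i_face, cb)

    rows.append(np.arange(N)); cols.append(np.arange(N)); vals.append(diag)
    a = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return a, diag


def _source_voxel(
    grid: VoxelGrid,
    geometry: MediumGeometry,
    musp_background: float,
) -> tuple[int, int, int]:
    """Voxel hosting the buried isotropic source.

    The beam enters at the boundary position and the equivalent source sits
    one transport mean free path 1/mu_s' along the inward normal.
    """
    pos = np.array(geometry.source_position_cm, dtype=float)
    side = grid.side_cm
    depth = 1.0 / musp_background
    normal = np.zeros(3)
    for axis in range(3):
        if abs(pos[axis]) < 1e-12:
            normal[axis] = 1.0
            break
        if abs(pos[axis] - side) < 1e-12:
            normal[axis] = -1.0
            break
    else:
        raise GeometryError(f"source position {tuple(pos)} is not on a face")
    buried = pos + depth * normal
    return tuple(grid.nearest_index(float(c)) for c in buried)


def solve_pde(
    medium: OpticalMedium,
    geometry: MediumGeometry,
    options: SolverOptions | None = None,
    source_power: float = 1.0,
    source_voxel: tuple[int, int, int] | None = None,
) -> FluenceField:
    """Solve the diffusion equation for the geometry's source.

    By default the boundary beam is buried one transport mean free path
    inside the entry face; ``source_voxel`` overrides this with an
    explicit isotropic point source (used e.g. for interior-source
    verification runs).

    Raises ConvergenceError (with the residual history attached) if CG
    does not reach the requested relative residual within the iteration cap.
    """
    options = options or SolverOptions()
    if np.any(medium.mua <= 0):
        raise ValueError("mua must be strictly positive everywhere")
    grid = medium.grid
    a, diag = _assemble(medium, options)
    musp_bg = float(medium.musp.ravel()[0])
    src = source_voxel or _source_voxel(grid, geometry, musp_bg)
    n = grid.cells_per_axis
    b = np.zeros(n**3)
    b[np.ravel_multi_index(src, (n, n, n))] = source_power

    m_inv = sp.diags(1.0 / diag)
    residuals: list[float] = []

    def _callback(xk):
        residuals.append(float(np.linalg.norm(b - a @ xk)))

    x, info = spla.cg(
        a, b, rtol=options.rtol, atol=0.0, maxiter=options.maxiter,
        M=m_inv, callback=_callback,
    )
    bnorm = float(np.linalg.norm(b))
    res = float(np.linalg.norm(b - a @ x)) / bnorm
    if info != 0:
        raise ConvergenceError(
            f"CG did not converge (info={info}); last residuals: "
            f"{[r / bnorm for r in residuals[-5:]]}"
        )
    phi = x.reshape(n, n, n)
    return FluenceField(
        grid=grid,
        phi=phi,
        source_position_cm=tuple(geometry.source_position_cm),
        source_voxel=src,
        iterations=len(residuals),
        residual=res,
        diagnostics={
            "rtol": options.rtol,
            "boundary": options.boundary,
            "d_convention": options.d_convention,
            "source_power": source_power,
        },
    )


def line_profile(field: FluenceField, y_cm: float, z_cm: float) -> pd.DataFrame:
    """Fluence along the x-parallel line through (., y, z).

    Returns columns x_cm, distance_cm (euclidean distance from the boundary
    source position) and phi.
    """
    grid = field.grid
    if not (0.0 <= y_cm <= grid.side_cm and 0.0 <= z_cm <= grid.side_cm):
        raise ValueError(f"line (y={y_cm}, z={z_cm}) lies outside the grid")
    j = grid.nearest_index(y_cm)
    k = grid.nearest_index(z_cm)
    x = grid.centers()
    sx, sy, sz = field.source_position_cm
    yc, zc = grid.centers()[j], grid.centers()[k]
    dist = np.sqrt((x - sx) ** 2 + (yc - sy) ** 2 + (zc - sz) ** 2)
    return pd.DataFrame({"x_cm": x, "distance_cm": dist, "phi": field.phi[:, j, k]})


def absorber_mean(field: FluenceField, geometry: MediumGeometry) -> float:
    """Arithmetic mean of the fluence over the absorber voxels."""
    mask = absorber_mask(field.grid, geometry)
    return float(field.phi[mask].mean())


def flux_balance(
    field: FluenceField, medium: OpticalMedium, options: SolverOptions | None = None
) -> dict:
    """Discrete energy budget: absorbed power + boundary out-flux vs source.

    For the converged field these should agree to well within a percent;
    the imbalance is the relative defect with respect to unit source power.
    """
    options = options or SolverOptions()
    h = medium.grid.spacing_cm
    absorbed = float(np.sum(medium.mua * field.phi) * h**3)
    a_factor = 1.0 if options.boundary == "matched" else extrapolation_factor(options.n_rel)
    outflux = 0.0
    for axis in range(3):
        for side in (0, -1):
            d_face = np.moveaxis(medium.d, axis, 0)[side]
            phi_face = np.moveaxis(field.phi, axis, 0)[side]
            cb = h**2 * 2.0 * d_face / (h + 4.0 * a_factor * d_face)
            outflux += float(np.sum(cb * phi_face))
    power = field.diagnostics.get("source_power", 1.0)
    return {
        "absorbed": absorbed,
        "boundary_outflux": outflux,
        "source_power": power,
        "imbalance": (absorbed + outflux - power) / power,
    }


def save_field(path, field: FluenceField, medium: OpticalMedium, **attrs) -> None:
    """Write the field and medium to HDF5 with a JSON diagnostics sidecar."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("phi", data=field.phi, dtype="f8")
        fh.create_dataset("mua", data=medium.mua, dtype="f8")
        fh.create_dataset("musp", data=medium.musp, dtype="f8")
        fh.attrs["h_cm"] = field.grid.spacing_cm
        fh.attrs["cube_cm"] = field.grid.side_cm
        fh.attrs["source_xyz_cm"] = field.source_position_cm
        for key, value in attrs.items():
            fh.attrs[key] = value
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "iterations": field.iterations,
                "residual": field.residual,
                **field.diagnostics,
            },
            fh,
            indent=2,
        )
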