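"""Material coefficient registry, medium geometry, and configuration I/O.

Thermodynamic coefficients are stored in SI units (kg, m, s, Pa, K).
Optical quantities use nm (wavelength, particle diameter) and the medium
geometry uses cm, the units customary in biomedical optics.  Each consuming
module converts exactly once at its own boundary, so every tabulated
constant is entered verbatim in its published units.

The built-in registry holds aqueous silica and alumina suspensions, the
two liquid tissue-phantom systems the forward model was designed around.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml


class ConfigError(ValueError):
    """A configuration file or object failed validation."""


class GeometryError(ValueError):
    """A medium geometry is inconsistent (grid, absorber, or source)."""


def _require_positive(obj: str, **fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0.0 and math.isfinite(value)):
            raise ConfigError(f"{obj}.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class PhaseCoefficients:
    """Thermodynamic coefficients of one phase (particle or base fluid).

    Attributes
    ----------
    rho : float
        Mass density [kg/m^3].
    c_heat : float
        Specific heat capacity at constant pressure [J/(kg K)].
    kappa : float
        Isothermal compressibility [1/Pa].
    beta : float
        Thermal (volumetric) expansion coefficient [1/K].
    """

    rho: float
    c_heat: float
    kappa: float
    beta: float

    def __post_init__(self) -> None:
        _require_positive(
            "PhaseCoefficients",
            rho=self.rho,
            c_heat=self.c_heat,
            kappa=self.kappa,
            beta=self.beta,
        )


@dataclass(frozen=True)
class OpticalCoefficients:
    """Refractive indices of the two phases at a single vacuum wavelength."""

    n_particle: float
    n_fluid: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.n_particle < 1.0 or self.n_fluid < 1.0:
            raise ConfigError(
                "refractive indices must be >= 1, got "
                f"n_particle={self.n_particle}, n_fluid={self.n_fluid}"
            )
        _require_positive("OpticalCoefficients", wavelength_nm=self.wavelength_nm)


@dataclass(frozen=True)
class SizeDistribution:
    """Particle size distribution used by the scattering calculations.

    ``monodisperse`` collapses to a single diameter.  ``lognormal`` models a
    polydisperse suspension with geometric mean ``mean_diameter_nm`` and
    geometric standard deviation ``geometric_sd``; it is discretized on a
    deterministic Gauss-Hermite quadrature in log-diameter so that repeated
    runs are bit-identical.
    """

    kind: str = "monodisperse"
    mean_diameter_nm: float = 100.0
    geometric_sd: float = 1.0
    n_quadrature_sizes: int = 21

    def __post_init__(self) -> None:
        if self.kind not in ("monodisperse", "lognormal"):
            raise ConfigError(f"unknown size distribution kind {self.kind!r}")
        _require_positive("SizeDistribution", mean_diameter_nm=self.mean_diameter_nm)
        if self.geometric_sd < 1.0:
            raise ConfigError(
                f"geometric_sd must be >= 1, got {self.geometric_sd}"
            )
        if self.n_quadrature_sizes < 1:
            raise ConfigError("n_quadrature_sizes must be >= 1")

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Diameters [nm] and number-fraction weights (summing to 1)."""
        if self.kind == "monodisperse" or self.geometric_sd == 1.0:
            return (
                np.array([self.mean_diameter_nm]),
                np.array([1.0]),
            )
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quadrature_sizes)
        sigma = math.log(self.geometric_sd)
        diameters = self.mean_diameter_nm * np.exp(math.sqrt(2.0) * sigma * nodes)
        w = weights / math.sqrt(math.pi)
        return diameters, w / w.sum()


@dataclass(frozen=True)
class SuspensionSpec:
    """Complete description of one colloidal suspension."""

    name: str
    particle: PhaseCoefficients
    fluid: PhaseCoefficients
    optics: OpticalCoefficients
    sizes: SizeDistribution


@dataclass(frozen=True)
class MediumGeometry:
    """Cubic voxelized medium with one cubic absorber and a boundary source.

    All lengths in cm; absorption coefficients in 1/cm.
    """

    cube_side_cm: float = 5.2
    grid_spacing_cm: float = 0.04
    absorber_side_cm: float = 0.8
    absorber_center_cm: tuple[float, float, float] = (2.6, 2.6, 2.6)
    mua_background_percm: float = 0.05
    mua_absorber_percm: float = 0.5
    source_position_cm: tuple[float, float, float] = (0.0, 2.6, 2.6)

    def __post_init__(self) -> None:
        _require_positive(
            "MediumGeometry",
            cube_side_cm=self.cube_side_cm,
            grid_spacing_cm=self.grid_spacing_cm,
            absorber_side_cm=self.absorber_side_cm,
            mua_background_percm=self.mua_background_percm,
            mua_absorber_percm=self.mua_absorber_percm,
        )
        ratio = self.cube_side_cm / self.grid_spacing_cm
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise GeometryError(
                f"cube side {self.cube_side_cm} cm is not an integer number of "
                f"cells at spacing {self.grid_spacing_cm} cm"
            )
        half = self.absorber_side_cm / 2.0
        for c in self.absorber_center_cm:
            if c - half < -1e-12 or c + half > self.cube_side_cm + 1e-12:
                raise GeometryError("absorber extends outside the cube")
        # the source must sit on one of the six faces
        on_face = any(
            abs(s) < 1e-12 or abs(s - self.cube_side_cm) < 1e-12
            for s in self.source_position_cm
        )
        inside = all(
            -1e-12 <= s <= self.cube_side_cm + 1e-12
            for s in self.source_position_cm
        )
        if not (on_face and inside):
            raise GeometryError(
                f"source position {self.source_position_cm} is not on a cube face"
            )

    @property
    def cells_per_axis(self) -> int:
        return int(round(self.cube_side_cm / self.grid_spacing_cm))


@dataclass(frozen=True)
class SolverOptions:
    """Numerical conventions of the photon diffusion solver.

    d_convention : ``"mua_plus_musp"`` for D = 1/[3(mua + musp)] or
        ``"musp_only"`` for D = 1/(3 musp).
    boundary : ``"robin"`` (partial-current with index-mismatch factor A
        derived from ``n_rel``) or ``"matched"`` (A = 1).
    """

    d_convention: str = "mua_plus_musp"
    boundary: str = "robin"
    n_rel: float = 1.33
    rtol: float = 1e-10
    maxiter: int = 50_000

    def __post_init__(self) -> None:
        if self.d_convention not in ("mua_plus_musp", "musp_only"):
            raise ConfigError(f"unknown d_convention {self.d_convention!r}")
        if self.boundary not in ("robin", "matched"):
            raise ConfigError(f"unknown boundary {self.boundary!r}")
        _require_positive("SolverOptions", n_rel=self.n_rel, rtol=self.rtol)


@dataclass(frozen=True)
class RunOptions:
    """Sweep-level options shared by the CLI and the pipeline."""

    etas: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 21))
    models: tuple[str, ...] = ("NO", "HS")
    reference_eta: float = 0.01
    n_angles: int = 256
    mixed_mode: bool = False
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        for eta in self.etas:
            if not 0.0 <= eta < 0.74:
                raise ConfigError(f"eta {eta} outside [0, 0.74)")
        for model in self.models:
            if model not in ("NO", "HS"):
                raise ConfigError(f"unknown model {model!r}")
        if self.n_angles < 8:
            raise ConfigError("n_angles must be >= 8")


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

WATER = PhaseCoefficients(rho=997.0, c_heat=4180.0, kappa=4.48e-10, beta=2.37e-4)

_SILICA_PARTICLE = PhaseCoefficients(
    rho=2190.0, c_heat=745.0, kappa=2.80e-11, beta=0.80e-6
)
_ALUMINA_PARTICLE = PhaseCoefficients(
    rho=3600.0, c_heat=775.0, kappa=3.94e-12, beta=0.85e-5
)


def load_registry() -> dict[str, SuspensionSpec]:
    """Built-in silica and alumina suspension specifications.

    Thermodynamic coefficients are the room-temperature literature values
    adopted for the phantom materials; the optical diameters (83 nm silica,
    55 nm alumina) are the mean diameters of the measured distributions at
    600 nm and are deliberately distinct from the diameters quoted for the
    thermodynamic coefficients.
    """
    return {
        "silica": SuspensionSpec(
            name="silica",
            particle=_SILICA_PARTICLE,
            fluid=WATER,
            optics=OpticalCoefficients(
                n_particle=1.470, n_fluid=1.332, wavelength_nm=600.0
            ),
            sizes=SizeDistribution(kind="monodisperse", mean_diameter_nm=83.0),
        ),
        "alumina": SuspensionSpec(
            name="alumina",
            particle=_ALUMINA_PARTICLE,
            fluid=WATER,
            optics=OpticalCoefficients(
                n_particle=1.768, n_fluid=1.332, wavelength_nm=600.0
            ),
            sizes=SizeDistribution(kind="monodisperse", mean_diameter_nm=55.0),
        ),
    }


def default_geometry() -> MediumGeometry:
    """The reference phantom: 5.2 cm cube, 0.04 cm grid (130 cells/axis),
    0.8 cm central absorber (mua 0.5/cm) in a 0.05/cm background, source
    on the x = 0 face at (0.0, 2.6, 2.6) cm."""
    return MediumGeometry()


def export_registry(path) -> None:
    """Write the built-in registry as a flat CSV (one row per phase)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["material", "phase", "rho", "c_heat", "kappa", "beta", "n", "mean_diameter_nm"]
        )
        for name, spec in load_registry().items():
            writer.writerow(
                [name, "particle", spec.particle.rho, spec.particle.c_heat,
                 spec.particle.kappa, spec.particle.beta,
                 spec.optics.n_particle, spec.sizes.mean_diameter_nm]
            )
            writer.writerow(
                [name, "fluid", spec.fluid.rho, spec.fluid.c_heat,
                 spec.fluid.kappa, spec.fluid.beta, spec.optics.n_fluid, ""]
            )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {where!r}")


def _phase_from_dict(d: dict, where: str) -> PhaseCoefficients:
    _check_keys(d, {"rho", "c_heat", "kappa", "beta"}, where)
    try:
        return PhaseCoefficients(**{k: float(d[k]) for k in ("rho", "c_heat", "kappa", "beta")})
    except KeyError as exc:
        raise ConfigError(f"missing coefficient {exc} in {where!r}") from None


def _material_from_dict(section: dict) -> SuspensionSpec:
    _check_keys(section, {"name", "particle", "fluid", "optics", "size"}, "material")
    registry = load_registry()
    name = section.get("name")
    if name is not None and name in registry:
        spec = registry[name]
    elif {"particle", "fluid", "optics"} <= set(section):
        opt = section["optics"]
        _check_keys(opt, {"n_particle", "n_fluid", "wavelength_nm"}, "material.optics")
        spec = SuspensionSpec(
            name=name or "custom",
            particle=_phase_from_dict(section["particle"], "material.particle"),
            fluid=_phase_from_dict(section["fluid"], "material.fluid"),
            optics=OpticalCoefficients(
                n_particle=float(opt["n_particle"]),
                n_fluid=float(opt["n_fluid"]),
                wavelength_nm=float(opt["wavelength_nm"]),
            ),
            sizes=SizeDistribution(),
        )
    else:
        raise ConfigError(
            f"material.name {name!r} is not in the registry and no full "
            "particle/fluid/optics specification was given"
        )
    if "size" in section:
        s = section["size"]
        _check_keys(
            s,
            {"kind", "mean_diameter_nm", "geometric_sd", "n_quadrature_sizes"},
            "material.size",
        )
        spec = replace(
            spec,
            sizes=SizeDistribution(
                kind=s.get("kind", spec.sizes.kind),
                mean_diameter_nm=float(s.get("mean_diameter_nm", spec.sizes.mean_diameter_nm)),
                geometric_sd=float(s.get("geometric_sd", 1.0)),
                n_quadrature_sizes=int(s.get("n_quadrature_sizes", 21)),
            ),
        )
    return spec


def _geometry_from_dict(section: dict) -> MediumGeometry:
    allowed = {
        "cube_side_cm", "grid_spacing_cm", "absorber_side_cm",
        "absorber_center_cm", "mua_background_percm", "mua_absorber_percm",
        "source_position_cm",
    }
    _check_keys(section, allowed, "geometry")
    default = MediumGeometry()
    kwargs: dict = {}
    for key in allowed:
        if key in section:
            value = section[key]
            if key.endswith("position_cm") or key.endswith("center_cm"):
                value = tuple(float(v) for v in value)
            else:
                value = float(value)
            kwargs[key] = value
    return replace(default, **kwargs)


def _run_from_dict(section: dict) -> RunOptions:
    allowed = {"etas", "models", "reference_eta", "n_angles", "mixed_mode", "solver"}
    _check_keys(section, allowed, "run")
    solver = SolverOptions()
    if "solver" in section:
        s = section["solver"]
        _check_keys(s, {"d_convention", "boundary", "n_rel", "rtol", "maxiter"}, "run.solver")
        solver = SolverOptions(
            d_convention=s.get("d_convention", solver.d_convention),
            boundary=s.get("boundary", solver.boundary),
            n_rel=float(s.get("n_rel", solver.n_rel)),
            rtol=float(s.get("rtol", solver.rtol)),
            maxiter=int(s.get("maxiter", solver.maxiter)),
        )
    default = RunOptions()
    return RunOptions(
        etas=tuple(float(e) for e in section.get("etas", default.etas)),
        models=tuple(section.get("models", default.models)),
        reference_eta=float(section.get("reference_eta", default.reference_eta)),
        n_angles=int(section.get("n_angles", default.n_angles)),
        mixed_mode=bool(section.get("mixed_mode", default.mixed_mode)),
        solver=solver,
    )


def load_config(path) -> tuple[SuspensionSpec, MediumGeometry, RunOptions]:
    """Parse and validate a YAML configuration file.

    The file has three optional sections, ``material``, ``geometry`` and
    ``run``; every omitted entry falls back to the reference-phantom
    defaults.  Unknown keys anywhere are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, {"material", "geometry", "run"}, "<top level>")
    spec = _material_from_dict(raw.get("material", {"name": "silica"}))
    geometry = _geometry_from_dict(raw.get("geometry", {}))
    run = _run_from_dict(raw.get("run", {}))
    return spec, geometry, run


def serialize_config(
    spec: SuspensionSpec, geometry: MediumGeometry, run: RunOptions
) -> dict:
    """Plain-dict form of a configuration, suitable for YAML round-trips."""
    return {
        "material": {
            "name": spec.name,
            "particle": {
                "rho": spec.particle.rho, "c_heat": spec.particle.c_heat,
                "kappa": spec.particle.kappa, "beta": spec.particle.beta,
            },
            "fluid": {
                "rho": spec.fluid.rho, "c_heat": spec.fluid.c_heat,
                "kappa": spec.fluid.kappa, "beta": spec.fluid.beta,
            },
            "optics": {
                "n_particle": spec.optics.n_particle,
                "n_fluid": spec.optics.n_fluid,
                "wavelength_nm": spec.optics.wavelength_nm,
            },
            "size": {
                "kind": spec.sizes.kind,
                "mean_diameter_nm": spec.sizes.mean_diameter_nm,
                "geometric_sd": spec.sizes.geometric_sd,
                "n_quadrature_sizes": spec.sizes.n_quadrature_sizes,
            },
        },
        "geometry": {
            "cube_side_cm": geometry.cube_side_cm,
            "grid_spacing_cm": geometry.grid_spacing_cm,
            "absorber_side_cm": geometry.absorber_side_cm,
            "absorber_center_cm": list(geometry.absorber_center_cm),
            "mua_background_percm": geometry.mua_background_percm,
            "mua_absorber_percm": geometry.mua_absorber_percm,
            "source_position_cm": list(geometry.source_position_cm),
        },
        "run": {
            "etas": list(run.etas),
            "models": list(run.models),
            "reference_eta": run.reference_eta,
            "n_angles": run.n_angles,
            "mixed_mode": run.mixed_mode,
            "solver": {
                "d_convention": run.solver.d_convention,
                "boundary": run.solver.boundary,
                "n_rel": run.solver.n_rel,
                "rtol": run.solver.rtol,
                "maxiter": run.solver.maxiter,
            },
        },
    }


def save_config(path, spec: SuspensionSpec, geometry: MediumGeometry, run: RunOptions) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_config(spec, geometry, run), fh, sort_keys=False)
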