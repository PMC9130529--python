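"""Volume-fraction dependence of suspension thermodynamics and the
Grueneisen parameter.

Two model families are provided, sharing the same two-phase mixing rules:

* ``NO`` (no interaction) -- the weight-based (WB) mixture for specific
  heat and thermal expansion together with the Urick (volume-based)
  mixture for compressibility.  Particles are treated as uncorrelated.
* ``HS`` (hard sphere) -- the same mixing rules applied after the
  particle-phase coefficients beta_p, C_p, kappa_p have been rescaled by
  the Carnahan-Starling packing-fraction factors, which encode the
  excluded-volume (hard-sphere) interaction between particles.

The mass density is a volume-weighted mixture in both families: hard-sphere
correlations rearrange particles but conserve mass.

The Grueneisen parameter Gamma = beta V^2 / C = beta / (rho kappa C) is the
dimensionless photoacoustic efficiency converting absorbed optical energy
density into initial pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import SuspensionSpec

#: hard-sphere close packing bound; CS polynomials are finite but
#: unphysical beyond it, so the whole eta domain is capped here.
ETA_MAX = 0.74

MODELS = ("NO", "HS")


class DomainError(ValueError):
    """Volume fraction outside the supported domain [0, ETA_MAX)."""


def _check_eta(eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0.0) or np.any(eta >= ETA_MAX):
        raise DomainError(f"volume fraction must lie in [0, {ETA_MAX}), got {eta}")
    return eta


def mixture_density(eta, spec: SuspensionSpec):
    """rho(eta) = eta rho_p + (1 - eta) rho_w  [kg/m^3]."""
    eta = _check_eta(eta)
    rho = eta * spec.particle.rho + (1.0 - eta) * spec.fluid.rho
    return rho if rho.ndim else float(rho)


def c_wb(eta, spec: SuspensionSpec):
    """Weight-based specific heat: mass-weighted mixture of C_p and C_w."""
    eta = _check_eta(eta)
    rho = eta * spec.particle.rho + (1.0 - eta) * spec.fluid.rho
    c = (
        eta * spec.particle.rho * spec.particle.c_heat
        + (1.0 - eta) * spec.fluid.rho * spec.fluid.c_heat
    ) / rho
    return c if c.ndim else float(c)


def beta_wb(eta, spec: SuspensionSpec):
    """Weight-based thermal expansion: mass-weighted mixture of beta."""
    eta = _check_eta(eta)
    rho = eta * spec.particle.rho + (1.0 - eta) * spec.fluid.rho
    b = (
        eta * spec.particle.rho * spec.particle.beta
        + (1.0 - eta) * spec.fluid.rho * spec.fluid.beta
    ) / rho
    return b if b.ndim else float(b)


def kappa_urick(eta, spec: SuspensionSpec):
    """Urick compressibility: volume-weighted mixture of kappa."""
    eta = _check_eta(eta)
    k = eta * spec.particle.kappa + (1.0 - eta) * spec.fluid.kappa
    return k if k.ndim else float(k)


def v_urick(eta, spec: SuspensionSpec):
    """Urick sound velocity V = [rho(eta) kappa_U(eta)]^(-1/2)  [m/s].

    Valid in the long-wavelength regime (acoustic wavelength much larger
    than the particle diameter)."""
    eta = _check_eta(eta)
    v = (mixture_density(eta, spec) * kappa_urick(eta, spec)) ** -0.5
    return v if np.ndim(v) else float(v)


@dataclass(frozen=True)
class CSFactors:
    """Carnahan-Starling packing-fraction factors at one volume fraction.

    The particle-phase coefficients entering the hard-sphere mixing rules
    are beta_p * f_beta, C_p * f_c and kappa_p * f_kappa.  All three equal
    1 at eta = 0, so the hard-sphere family reduces to the no-interaction
    family in the dilute limit.
    """

    f_beta: float
    f_c: float
    f_kappa: float


def cs_factors(eta):
    """Evaluate the Carnahan-Starling factors.

    With P(eta) = 1 - 2 eta^3 + eta^4 and
    Q(eta) = 1 + 4 eta + 4 eta^2 - 4 eta^3 + eta^4:

    * f_beta  = P / Q
    * f_c     = P^2 / [Q (1 - eta)^4]
    * f_kappa = (1 - eta)^4 / Q
    """
    eta = _check_eta(eta)
    p = 1.0 - 2.0 * eta**3 + eta**4
    q = 1.0 + 4.0 * eta + 4.0 * eta**2 - 4.0 * eta**3 + eta**4
    one4 = (1.0 - eta) ** 4
    f_beta = p / q
    f_c = p**2 / (q * one4)
    f_kappa = one4 / q
    if eta.ndim:
        return CSFactors(f_beta=f_beta, f_c=f_c, f_kappa=f_kappa)
    return CSFactors(f_beta=float(f_beta), f_c=float(f_c), f_kappa=float(f_kappa))


def beta_wcs(eta, spec: SuspensionSpec):
    """Hard-sphere thermal expansion: WB mixing with beta_p -> beta_p f_beta."""
    eta = _check_eta(eta)
    f = cs_factors(eta).f_beta
    rho = eta * spec.particle.rho + (1.0 - eta) * spec.fluid.rho
    b = (
        eta * spec.particle.rho * spec.particle.beta * f
        + (1.0 - eta) * spec.fluid.rho * spec.fluid.beta
    ) / rho
    return b if np.ndim(b) else float(b)


def c_wcs(eta, spec: SuspensionSpec):
    """Hard-sphere specific heat: WB mixing with C_p -> C_p f_c."""
    eta = _check_eta(eta)
    f = cs_factors(eta).f_c
    rho = eta * spec.particle.rho + (1.0 - eta) * spec.fluid.rho
    c = (
        eta * spec.particle.rho * spec.particle.c_heat * f
        + (1.0 - eta) * spec.fluid.rho * spec.fluid.c_heat
    ) / rho
    return c if np.ndim(c) else float(c)


def kappa_ucs(eta, spec: SuspensionSpec):
    """Hard-sphere compressibility: Urick mixing with kappa_p -> kappa_p f_kappa."""
    eta = _check_eta(eta)
    f = cs_factors(eta).f_kappa
    k = eta * spec.particle.kappa * f + (1.0 - eta) * spec.fluid.kappa
    return k if np.ndim(k) else float(k)


def v_ucs(eta, spec: SuspensionSpec):
    """Hard-sphere sound velocity V = [rho kappa_UCS]^(-1/2)  [m/s]."""
    v = (mixture_density(eta, spec) * kappa_ucs(eta, spec)) ** -0.5
    return v if np.ndim(v) else float(v)


@dataclass(frozen=True)
class ThermoState:
    """All volume-fraction-dependent thermodynamic properties at one eta."""

    eta: float
    model: str
    rho: float        # kg/m^3
    c_heat: float     # J/(kg K)
    beta: float       # 1/K
    kappa: float      # 1/Pa
    v_sound: float    # m/s
    gamma: float      # dimensionless


def thermo_state(eta: float, spec: SuspensionSpec, model: str = "NO") -> ThermoState:
    """Assemble the consistent thermodynamic state for one model family.

    ``gamma`` is evaluated as beta / (rho kappa c_heat); by construction
    v_sound = (rho kappa)^(-1/2), so this coincides with beta v^2 / c_heat.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    eta = float(_check_eta(eta))
    rho = mixture_density(eta, spec)
    if model == "NO":
        c = c_wb(eta, spec)
        beta = beta_wb(eta, spec)
        kappa = kappa_urick(eta, spec)
    else:
        c = c_wcs(eta, spec)
        beta = beta_wcs(eta, spec)
        kappa = kappa_ucs(eta, spec)
    v = (rho * kappa) ** -0.5
    gamma = beta / (rho * kappa * c)
    return ThermoState(
        eta=eta, model=model, rho=rho, c_heat=c, beta=beta,
        kappa=kappa, v_sound=v, gamma=gamma,
    )


def water_state(spec: SuspensionSpec) -> ThermoState:
    """Pure base-fluid state (eta = 0); the normalization reference."""
    return thermo_state(0.0, spec, "NO")


_QUANTITIES = ("rho", "c_heat", "beta", "kappa", "v_sound", "gamma")


def sweep_thermo(
    etas, spec: SuspensionSpec, models=MODELS
) -> pd.DataFrame:
    """Tabulate thermodynamic states over a volume-fraction grid.

    Returns one row per (eta, model) with the raw quantities, the
    water-normalized columns ``*_normalized`` and, when both families are
    requested, the relative-difference columns ``rd_*`` defined as the
    normalized no-interaction result minus the normalized hard-sphere
    result at the same eta.
    """
    ref = water_state(spec)
    rows = []
    for eta in np.atleast_1d(np.asarray(etas, dtype=float)):
        for model in models:
            state = thermo_state(float(eta), spec, model)
            row = {"eta": state.eta, "model": model, "material": spec.name}
            for name in _QUANTITIES:
                value = getattr(state, name)
                row[name] = value
                row[f"{name}_normalized"] = value / getattr(ref, name)
            rows.append(row)
    df = pd.DataFrame(rows)
    if set(models) >= {"NO", "HS"}:
        for name in _QUANTITIES:
            pivot = df.pivot(index="eta", columns="model", values=f"{name}_normalized")
            rd = (pivot["NO"] - pivot["HS"]).rename(f"rd_{name}")
            df = df.merge(rd, left_on="eta", right_index=True, how="left")
    return df
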