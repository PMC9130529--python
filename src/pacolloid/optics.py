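"""Microscopic light-scattering properties of colloidal suspensions.

Three layers:

* Lorenz-Mie scattering by a single homogeneous sphere (amplitudes,
  differential cross section, total cross section, anisotropy factor).
* The Percus-Yevick (Wertheim) hard-sphere static structure factor S(q),
  describing the far-field interference of the fields scattered by
  correlated particles.
* Suspension-level coefficients under two theories:

  - IST (independent scattering): per-particle cross sections summed
    without interference, so mu_s is exactly linear in volume fraction
    at fixed particle sizes.
  - DST (dependent scattering): the single-particle differential cross
    section is weighted by S(q) with momentum transfer
    q = 2 k sin(theta/2), k = 2 pi n_fluid / lambda, before the angular
    integration.  At packing fractions of a few percent and above this
    suppresses small-angle scattering and hence mu_s'.

Cross sections are in nm^2, momentum transfer in 1/nm, and the suspension
coefficients mu_s, mu_s' in 1/cm.  Polydisperse suspensions are handled in
the local-monodisperse approximation: each size scatters with the
structure factor of a hard-sphere fluid of its own diameter at the total
volume fraction, and contributions are number-fraction weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import OpticalCoefficients, SuspensionSpec
from .thermo import DomainError, ETA_MAX

THEORIES = ("IST", "DST")


# ---------------------------------------------------------------------------
# Lorenz-Mie single sphere
# ---------------------------------------------------------------------------

def mie_coefficients(x: float, m: complex) -> tuple[np.ndarray, np.ndarray]:
    """Mie expansion coefficients a_n, b_n, n = 1..nmax.

    nmax follows the Wiscombe criterion x + 4 x^(1/3) + 2.  The
    logarithmic derivative D_n(mx) is generated by downward recurrence,
    the Riccati-Bessel functions psi_n, chi_n by upward recurrence.
    """
    if x <= 0:
        raise DomainError(f"size parameter must be positive, got {x}")
    nmax = max(int(round(x + 4.0 * x ** (1.0 / 3.0) + 2.0)), 3)
    mx = m * x
    nmx = max(nmax, int(abs(mx))) + 16
    d = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi[0] = math.cos(x), math.sin(x)          # psi_{-1}, psi_0
    chi_m1, chi[0] = -math.sin(x), math.cos(x)         # chi_{-1}, chi_0
    for n in range(1, nmax + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - (psi_m1 if n == 1 else psi[n - 2])
        chi[n] = (2 * n - 1) / x * chi[n - 1] - (chi_m1 if n == 1 else chi[n - 2])
    xi = psi - 1j * chi

    n = np.arange(1, nmax + 1)
    dn = d[1 : nmax + 1]
    fa = dn / m + n / x
    fb = dn * m + n / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return a, b


def _pi_tau(mu: np.ndarray, nmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n(mu), tau_n(mu) for n = 1..nmax."""
    pi = np.zeros((nmax + 1, mu.size))
    tau = np.zeros((nmax + 1, mu.size))
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, nmax + 1):
        pi[n] = ((2 * n - 1) * mu * pi[n - 1] - n * pi[n - 2]) / (n - 1)
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def mie_amplitudes(x: float, m: complex, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(mu), S2(mu) on the given cos(theta) nodes."""
    a, b = mie_coefficients(x, m)
    nmax = a.size
    pi_n, tau_n = _pi_tau(np.asarray(mu, dtype=float), nmax)
    n = np.arange(1, nmax + 1)
    w = ((2 * n + 1) / (n * (n + 1)))[:, None]
    s1 = (w * (a[:, None] * pi_n + b[:, None] * tau_n)).sum(axis=0)
    s2 = (w * (a[:, None] * tau_n + b[:, None] * pi_n)).sum(axis=0)
    return s1, s2


def mie_series_cross_section(x: float, m: complex, k: float) -> tuple[float, float]:
    """Closed-form series values (sigma_s [nm^2], g) from the Mie sums.

    Used as an internal consistency reference for the quadrature route.
    """
    a, b = mie_coefficients(x, m)
    n = np.arange(1, a.size + 1)
    csca = 2.0 * math.pi / k**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    asy = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = 4.0 * math.pi / k**2 * asy / csca
    return float(csca), float(g)


@dataclass(frozen=True)
class MieSolution:
    """Single-particle scattering solution on an angular quadrature.

    ``diff_cs`` is the unpolarized differential cross section
    d sigma/d Omega [nm^2/sr] at the Gauss-Legendre nodes ``mu`` = cos(theta);
    ``phase`` is diff_cs / sigma_s, normalized so that its solid-angle
    integral is 1.
    """

    x: float
    m: float
    wavelength_nm: float
    diameter_nm: float
    k_per_nm: float
    mu: np.ndarray
    weights: np.ndarray
    diff_cs: np.ndarray
    cross_section_nm2: float
    g0: float

    @property
    def phase(self) -> np.ndarray:
        return self.diff_cs / self.cross_section_nm2


def mie_solve(
    diameter_nm: float, optics: OpticalCoefficients, n_angles: int = 256
) -> MieSolution:
    """Solve single-sphere scattering for a particle in the base fluid.

    The size parameter is x = pi d n_fluid / lambda and the relative index
    m = n_particle / n_fluid; the wavenumber k = 2 pi n_fluid / lambda is
    the one inside the fluid.  The total cross section and anisotropy
    factor are obtained by Gauss-Legendre quadrature of the differential
    cross section over cos(theta).
    """
    if diameter_nm <= 0:
        raise DomainError(f"diameter must be positive, got {diameter_nm}")
    x = math.pi * diameter_nm * optics.n_fluid / optics.wavelength_nm
    m = optics.n_particle / optics.n_fluid
    k = 2.0 * math.pi * optics.n_fluid / optics.wavelength_nm
    mu, w = np.polynomial.legendre.leggauss(n_angles)
    s1, s2 = mie_amplitudes(x, m, mu)
    diff_cs = (np.abs(s1) ** 2 + np.abs(s2) ** 2) / (2.0 * k**2)
    csca = 2.0 * math.pi * np.sum(w * diff_cs)
    g0 = 2.0 * math.pi * np.sum(w * mu * diff_cs) / csca
    return MieSolution(
        x=x, m=m, wavelength_nm=optics.wavelength_nm, diameter_nm=diameter_nm,
        k_per_nm=k, mu=mu, weights=w, diff_cs=diff_cs,
        cross_section_nm2=float(csca), g0=float(g0),
    )


def rayleigh_cross_section(diameter_nm: float, optics: OpticalCoefficients) -> float:
    """Rayleigh (small-sphere) limit of the scattering cross section [nm^2]."""
    x = math.pi * diameter_nm * optics.n_fluid / optics.wavelength_nm
    m = optics.n_particle / optics.n_fluid
    lorentz = (m**2 - 1.0) / (m**2 + 2.0)
    return (8.0 / 3.0) * x**4 * abs(lorentz) ** 2 * math.pi * (diameter_nm / 2.0) ** 2


# ---------------------------------------------------------------------------
# Percus-Yevick hard-sphere structure factor
# ---------------------------------------------------------------------------

_PY_NODES, _PY_WEIGHTS = np.polynomial.legendre.leggauss(128)
_PY_S = 0.5 * (_PY_NODES + 1.0)       # quadrature on s = r/d in [0, 1]
_PY_W = 0.5 * _PY_WEIGHTS


@dataclass(frozen=True)
class StructureFactorModel:
    """Percus-Yevick hard-sphere static structure factor at one packing.

    Calling the model evaluates S(q) for momentum transfer q [1/nm].  The
    direct correlation function inside the core,
    c(s) = -(alpha + beta s + gamma s^3) with s = r/d, is transformed by a
    fixed Gauss-Legendre quadrature; the q -> 0 limit is then automatic
    and the evaluation is stable at all q.
    """

    eta: float
    diameter_nm: float
    alpha: float
    beta: float
    gamma: float

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        u = q * self.diameter_nm                       # u = q d
        s = _PY_S
        poly = (self.alpha + self.beta * s + self.gamma * s**3) * s**2
        # sin(u s)/(u s) via np.sinc, stable through u = 0
        sinc = np.sinc(np.multiply.outer(u, s) / math.pi)
        integral = sinc @ (poly * _PY_W)
        n0c = -24.0 * self.eta * integral
        out = 1.0 / (1.0 - n0c)
        return out if out.ndim else float(out)


def py_structure_factor(eta: float, diameter_nm: float) -> StructureFactorModel:
    """Construct the PY (Wertheim) structure factor for hard spheres."""
    if not 0.0 <= eta < ETA_MAX:
        raise DomainError(f"packing fraction must lie in [0, {ETA_MAX}), got {eta}")
    if diameter_nm <= 0:
        raise DomainError(f"diameter must be positive, got {diameter_nm}")
    one = (1.0 - eta) ** 4
    alpha = (1.0 + 2.0 * eta) ** 2 / one
    beta = -6.0 * eta * (1.0 + 0.5 * eta) ** 2 / one
    gamma = 0.5 * eta * alpha
    return StructureFactorModel(
        eta=eta, diameter_nm=diameter_nm, alpha=alpha, beta=beta, gamma=gamma
    )


# ---------------------------------------------------------------------------
# Suspension-level coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringProperties:
    """Bulk scattering coefficients of a suspension at one volume fraction."""

    eta: float
    theory: str
    mus_percm: float
    g: float
    musp_percm: float
    number_density_percm3: float


def scattering_properties(
    eta: float, spec: SuspensionSpec, theory: str = "DST", n_angles: int = 256
) -> ScatteringProperties:
    """Compute mu_s, g and mu_s' = mu_s (1 - g) for a suspension.

    The particle number density follows from the volume fraction and the
    (number-fraction weighted) particle volume.  Under the IST the
    per-particle cross section is the bare Mie one; under the DST the
    differential cross section is weighted by the PY structure factor
    evaluated at q(theta) = 2 k sin(theta/2) before integration.
    """
    if theory not in THEORIES:
        raise ValueError(f"theory must be one of {THEORIES}, got {theory!r}")
    if not 0.0 < eta < ETA_MAX:
        raise DomainError(f"volume fraction must lie in (0, {ETA_MAX}), got {eta}")
    diameters, fractions = spec.sizes.quadrature()
    volumes = math.pi * diameters**3 / 6.0                     # nm^3
    n_total = eta / float(np.sum(fractions * volumes))         # 1/nm^3

    sigma_tot = 0.0   # sum_i n_i sigma_i / n_total        [nm^2]
    sigma_mu = 0.0    # same, weighted by cos(theta)
    for d_nm, f in zip(diameters, fractions):
        sol = mie_solve(float(d_nm), spec.optics, n_angles=n_angles)
        if theory == "IST":
            weight = 1.0
        else:
            q = sol.k_per_nm * np.sqrt(2.0 * np.clip(1.0 - sol.mu, 0.0, None))
            weight = py_structure_factor(eta, float(d_nm))(q)
        integrand = sol.diff_cs * weight
        sigma = 2.0 * math.pi * np.sum(sol.weights * integrand)
        sigma_g = 2.0 * math.pi * np.sum(sol.weights * sol.mu * integrand)
        sigma_tot += f * sigma
        sigma_mu += f * sigma_g

    g = sigma_mu / sigma_tot
    mus_per_nm = n_total * sigma_tot
    mus_percm = mus_per_nm * 1.0e7                             # 1 cm = 1e7 nm
    return ScatteringProperties(
        eta=eta,
        theory=theory,
        mus_percm=float(mus_percm),
        g=float(g),
        musp_percm=float(mus_percm * (1.0 - g)),
        number_density_percm3=float(n_total * 1.0e21),
    )


def sweep_musp(
    etas,
    spec: SuspensionSpec,
    n_angles: int = 256,
    reference_eta: float = 0.01,
) -> pd.DataFrame:
    """Tabulate mu_s' under both theories over a volume-fraction grid.

    ``nr`` columns are normalized by the IST value at ``reference_eta``
    (the dilute anchor at which both theories coincide); ``rd`` is
    nr(IST) - nr(DST).
    """
    ref = scattering_properties(reference_eta, spec, "IST", n_angles).musp_percm
    rows = []
    for eta in np.atleast_1d(np.asarray(etas, dtype=float)):
        row = {"eta": float(eta), "material": spec.name}
        for theory in THEORIES:
            props = scattering_properties(float(eta), spec, theory, n_angles)
            row[f"mus_percm_{theory.lower()}"] = props.mus_percm
            row[f"g_{theory.lower()}"] = props.g
            row[f"musp_percm_{theory.lower()}"] = props.musp_percm
            row[f"nr_{theory.lower()}"] = props.musp_percm / ref
        row["rd"] = row["nr_ist"] - row["nr_dst"]
        rows.append(row)
    return pd.DataFrame(rows)
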