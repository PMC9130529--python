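"""Initial photoacoustic pressure: p0(r) = Gamma(eta) mua(r) Phi(r).

Two self-consistent model stacks are assembled:

* HS  -- hard-sphere Grueneisen parameter (Carnahan-Starling factors)
  paired with the dependent-scattering (DST) fluence;
* NO  -- no-interaction Grueneisen parameter paired with the
  independent-scattering (IST) fluence.

The pairing is enforced: combining, say, HS thermodynamics with an IST
fluence is an ablation experiment and must be requested explicitly.

Since the absorption map is volume-fraction independent, the decrease of
the mean absorber pressure p_a relative to a dilute reference splits
exactly into a Grueneisen term and a fluence term:

    -log10[pa(eta)/pa(ref)]
        = -log10[Gamma(eta)/Gamma(ref)] - log10[Phi_a(eta)/Phi_a(ref)]

which is the decomposition reported by :func:`decompose_pa`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fluence as fl
from . import optics, thermo
from .materials import MediumGeometry, RunOptions, SuspensionSpec

#: thermodynamic model -> scattering theory of the same physical family
PAIRING = {"HS": "DST", "NO": "IST"}


class PairingError(ValueError):
    """A thermodynamic model was combined with the wrong scattering theory."""


@dataclass(frozen=True)
class PressureField:
    """Voxelwise initial pressure in arbitrary units (unit source power)."""

    grid: fl.VoxelGrid
    p0: np.ndarray
    model: str
    theory: str
    eta: float
    material: str
    gamma: float


def assemble_p0(
    state: thermo.ThermoState,
    medium: fl.OpticalMedium,
    field: fl.FluenceField,
    theory: str,
    material: str = "",
    mixed_mode: bool = False,
) -> PressureField:
    """Voxelwise product p0 = Gamma mua Phi with provenance checks."""
    if medium.grid != field.grid:
        raise ValueError("medium and fluence field are on different grids")
    if PAIRING[state.model] != theory and not mixed_mode:
        raise PairingError(
            f"{state.model} thermodynamics expects the {PAIRING[state.model]} "
            f"fluence, got {theory}; pass mixed_mode=True for ablation runs"
        )
    return PressureField(
        grid=field.grid,
        p0=state.gamma * medium.mua * field.phi,
        model=state.model,
        theory=theory,
        eta=state.eta,
        material=material,
        gamma=state.gamma,
    )


def pa_summary(field: PressureField, geometry: MediumGeometry) -> float:
    """Mean initial pressure over the absorber voxels."""
    mask = fl.absorber_mask(field.grid, geometry)
    return float(field.p0[mask].mean())


def decompose_pa(summary: pd.DataFrame, reference_eta: float = 0.01) -> pd.DataFrame:
    """Split the log-decrease of p_a into Grueneisen and fluence terms.

    ``summary`` must carry columns eta, model, gamma, phi_a, p_a (one row
    per (eta, model)).  Adds, per model, the total decadic log-decrease
    relative to the reference volume fraction, its two components, and the
    percentage share of each component.
    """
    out = summary.copy()
    for col in ("log_decrease_total", "log_decrease_gamma", "log_decrease_phi",
                "gamma_share_pct", "phi_share_pct"):
        out[col] = np.nan
    for model, group in summary.groupby("model"):
        ref = group[np.isclose(group["eta"], reference_eta)]
        if ref.empty:
            raise ValueError(
                f"reference eta {reference_eta} missing from sweep for model {model}"
            )
        g0 = float(ref["gamma"].iloc[0])
        phi0 = float(ref["phi_a"].iloc[0])
        pa0 = float(ref["p_a"].iloc[0])
        sel = out["model"] == model
        total = -np.log10(out.loc[sel, "p_a"] / pa0)
        g_term = -np.log10(out.loc[sel, "gamma"] / g0)
        phi_term = -np.log10(out.loc[sel, "phi_a"] / phi0)
        out.loc[sel, "log_decrease_total"] = total
        out.loc[sel, "log_decrease_gamma"] = g_term
        out.loc[sel, "log_decrease_phi"] = phi_term
        with np.errstate(invalid="ignore", divide="ignore"):
            out.loc[sel, "gamma_share_pct"] = 100.0 * g_term / total
            out.loc[sel, "phi_share_pct"] = 100.0 * phi_term / total
    return out


def run_single(
    eta: float,
    spec: SuspensionSpec,
    geometry: MediumGeometry,
    model: str,
    options: RunOptions | None = None,
) -> dict:
    """One (eta, model) pipeline stage: thermo -> mu_s' -> fluence -> p_a."""
    options = options or RunOptions()
    theory = PAIRING[model]
    state = thermo.thermo_state(eta, spec, model)
    props = optics.scattering_properties(eta, spec, theory, options.n_angles)
    medium = fl.build_medium(geometry, props.musp_percm, options.solver.d_convention)
    field = fl.solve_pde(medium, geometry, options.solver)
    p0 = assemble_p0(state, medium, field, theory, material=spec.name,
                     mixed_mode=options.mixed_mode)
    phi_a = fl.absorber_mean(field, geometry)
    return {
        "eta": eta,
        "model": model,
        "theory": theory,
        "material": spec.name,
        "gamma": state.gamma,
        "musp_percm": props.musp_percm,
        "g": props.g,
        "phi_a": phi_a,
        "p_a": pa_summary(p0, geometry),
        "solver_iterations": field.iterations,
        "solver_residual": field.residual,
    }


def run_sweep(
    spec: SuspensionSpec,
    geometry: MediumGeometry,
    options: RunOptions | None = None,
) -> pd.DataFrame:
    """Full volume-fraction sweep over the requested model stacks.

    Returns one row per (eta, model) including the normalized absorber
    pressure and, when the reference volume fraction is part of the grid,
    the logarithmic decomposition columns.  The computation is
    deterministic: re-running with an identical configuration reproduces
    the table exactly.
    """
    options = options or RunOptions()
    rows = [
        run_single(float(eta), spec, geometry, model, options)
        for eta in options.etas
        for model in options.models
    ]
    df = pd.DataFrame(rows)
    if any(np.isclose(options.reference_eta, options.etas)):
        df = decompose_pa(df, options.reference_eta)
        for model, group in df.groupby("model"):
            ref_pa = float(
                group.loc[np.isclose(group["eta"], options.reference_eta), "p_a"].iloc[0]
            )
            df.loc[df["model"] == model, "pa_normalized"] = df.loc[
                df["model"] == model, "p_a"
            ] / ref_pa
    return df
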