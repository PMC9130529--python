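"""Mixture thermodynamics and the Grueneisen parameter.

The Carnahan-Starling factors are checked against an independent symbolic
evaluation of the packing-fraction polynomials (sympy with exact
rationals); the mixture formulas are checked against frozen hand-evaluated
values and their water limits.
"""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from pacolloid import thermo
from pacolloid.thermo import (
    DomainError,
    beta_wb,
    c_wb,
    cs_factors,
    kappa_urick,
    mixture_density,
    sweep_thermo,
    thermo_state,
    v_urick,
    water_state,
)

ETAS = st.floats(min_value=0.0, max_value=0.73, allow_nan=False)


# ---------------------------------------------------------------------------
# no-interaction mixtures: frozen hand evaluations of the mixing rules
# ---------------------------------------------------------------------------

def test_density_mixture(silica):
    assert mixture_density(0.0, silica) == pytest.approx(997.0)
    assert mixture_density(0.2, silica) == pytest.approx(1235.6)


def test_density_rejects_pure_particle_phase(silica):
    with pytest.raises(DomainError):
        mixture_density(1.0, silica)
    with pytest.raises(DomainError):
        mixture_density(-0.01, silica)


def test_water_limits(silica):
    assert c_wb(0.0, silica) == pytest.approx(4180.0)
    assert beta_wb(0.0, silica) == pytest.approx(2.37e-4)
    assert kappa_urick(0.0, silica) == pytest.approx(4.48e-10)
    # (rho_w kappa_w)^(-1/2) evaluated independently
    assert v_urick(0.0, silica) == pytest.approx((997.0 * 4.48e-10) ** -0.5)
    assert v_urick(0.0, silica) == pytest.approx(1496.3, abs=0.1)


def test_urick_compressibility_at_20pct(silica):
    # 0.2 * 2.80e-11 + 0.8 * 4.48e-10
    assert kappa_urick(0.2, silica) == pytest.approx(3.640e-10, rel=1e-4)


def test_wb_expansion_at_20pct(silica):
    # (0.2*2190*0.8e-6 + 0.8*997*2.37e-4) / 1235.6
    assert beta_wb(0.2, silica) == pytest.approx(1.5327e-4, rel=1e-4)


def test_silica_sound_velocity_non_monotone(silica):
    """The silica V(eta) curve dips in the 1-10% range then rises by 20%,
    because rho*kappa passes through a minimum."""
    etas = np.linspace(0.0, 0.2, 41)
    v = np.array([v_urick(e, silica) for e in etas])
    assert v[10] < v[0]  # eta = 0.05
    assert v[-1] > v.min()
    assert np.argmin(v) not in (0, len(v) - 1)


# ---------------------------------------------------------------------------
# Carnahan-Starling factors
# ---------------------------------------------------------------------------

def test_cs_factors_unity_at_zero():
    f = cs_factors(0.0)
    assert (f.f_beta, f.f_c, f.f_kappa) == (1.0, 1.0, 1.0)


def test_cs_factors_frozen_values():
    f = cs_factors(0.2)
    assert f.f_beta == pytest.approx(0.51078, abs=1e-5)
    assert f.f_kappa == pytest.approx(0.21227, abs=1e-5)


def test_cs_factors_against_symbolic_oracle():
    """Independent sympy evaluation of the printed polynomial ratios at
    random packing fractions."""
    x = sympy.Symbol("x")
    p = 1 - 2 * x**3 + x**4
    q = 1 + 4 * x + 4 * x**2 - 4 * x**3 + x**4
    f_beta_s = p / q
    f_c_s = p**2 / (q * (1 - x) ** 4)
    f_kappa_s = (1 - x) ** 4 / q
    rng = np.random.default_rng(20220514)
    for eta in rng.uniform(0.0, 0.5, size=50):
        f = cs_factors(float(eta))
        r = sympy.Rational(eta)
        assert f.f_beta == pytest.approx(float(f_beta_s.subs(x, r)), rel=1e-12)
        assert f.f_c == pytest.approx(float(f_c_s.subs(x, r)), rel=1e-12)
        assert f.f_kappa == pytest.approx(float(f_kappa_s.subs(x, r)), rel=1e-12)


def test_f_kappa_strictly_decreasing():
    etas = np.linspace(0.0, 0.73, 200)
    f = cs_factors(etas).f_kappa
    assert np.all(np.diff(f) < 0)


# ---------------------------------------------------------------------------
# assembled states
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", ["NO", "HS"])
@pytest.mark.parametrize("material", ["silica", "alumina"])
def test_state_water_limit(registry, material, model):
    state = thermo_state(0.0, registry[material], model)
    w = water_state(registry[material])
    assert state.gamma == pytest.approx(w.gamma, rel=1e-14)
    assert state.gamma == pytest.approx(
        2.37e-4 / (997.0 * 4.48e-10 * 4180.0), rel=1e-14
    )


def test_hs_equals_no_at_zero(silica):
    no = thermo_state(0.0, silica, "NO")
    hs = thermo_state(0.0, silica, "HS")
    assert no.gamma == hs.gamma
    assert no.kappa == hs.kappa


@settings(max_examples=60, deadline=None)
@given(eta=ETAS, model=st.sampled_from(["NO", "HS"]))
def test_state_internal_consistency(registry, eta, model):
    """v^2 rho kappa = 1 and the two Gamma evaluation paths agree."""
    state = thermo_state(eta, registry["silica"], model)
    assert state.v_sound**2 * state.rho * state.kappa == pytest.approx(1.0, rel=1e-12)
    gamma_v = state.beta * state.v_sound**2 / state.c_heat
    assert state.gamma == pytest.approx(gamma_v, rel=1e-12)
    assert state.gamma > 0


@settings(max_examples=40, deadline=None)
@given(eta=ETAS)
def test_mass_conservation_across_models(registry, eta):
    no = thermo_state(eta, registry["alumina"], "NO")
    hs = thermo_state(eta, registry["alumina"], "HS")
    assert no.rho == hs.rho


@pytest.mark.parametrize("material", ["silica", "alumina"])
@pytest.mark.parametrize("model", ["NO", "HS"])
def test_normalized_c_and_beta_strictly_decrease(registry, material, model):
    spec = registry[material]
    etas = np.linspace(0.0, 0.2, 21)
    c = np.array([thermo_state(e, spec, model).c_heat for e in etas])
    b = np.array([thermo_state(e, spec, model).beta for e in etas])
    assert np.all(np.diff(c) < 0)
    assert np.all(np.diff(b) < 0)


def test_domain_enforced_at_close_packing(silica):
    with pytest.raises(DomainError):
        thermo_state(0.74, silica, "NO")
    thermo_state(0.7399, silica, "HS")  # just inside the domain


# ---------------------------------------------------------------------------
# sweep table
# ---------------------------------------------------------------------------

def test_sweep_normalization_and_rd(silica):
    df = sweep_thermo(np.arange(0.01, 0.21, 0.01), silica)
    assert len(df) == 40
    near_zero = sweep_thermo([1e-9], silica)
    assert near_zero["rd_c_heat"].abs().max() < 1e-8

    row = df[(np.isclose(df["eta"], 0.2)) & (df["model"] == "NO")].iloc[0]
    # printed trends: C/Cw ~ 0.7, beta/betaw ~ 0.65, normalized Gamma ~ 0.90
    assert row["c_heat_normalized"] == pytest.approx(0.7, abs=0.02)
    assert row["beta_normalized"] == pytest.approx(0.65, abs=0.02)
    assert row["gamma_normalized"] - 1.0 == pytest.approx(-0.10, abs=0.01)
    # hard-sphere C falls less steeply: NO minus HS normalized C is negative
    assert row["rd_c_heat"] < 0
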