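"""Photon diffusion solver: analytic oracle, conservation, and behavior.

The quantitative oracle is the infinite-medium Green's function
Phi(r) = exp(-mu_eff r) / (4 pi D r) with mu_eff = sqrt(3 mua (mua + mus')),
checked with an interior point source far from the boundaries.
"""

import numpy as np
import pytest

from pacolloid import fluence as fl
from pacolloid.materials import MediumGeometry, SolverOptions
from pacolloid.optics import scattering_properties


@pytest.fixture(scope="module")
def homogeneous_solution():
    """Interior point source in a homogeneous medium on an 80-cell grid."""
    geo = MediumGeometry(
        cube_side_cm=5.2, grid_spacing_cm=0.065, absorber_side_cm=0.78,
        mua_background_percm=0.05, mua_absorber_percm=0.05,
        source_position_cm=(0.0, 2.6, 2.6),
    )
    medium = fl.build_medium(geo, musp_percm=15.0)
    c = medium.grid.cells_per_axis // 2
    field = fl.solve_pde(medium, geo, SolverOptions(), source_voxel=(c, c, c))
    return geo, medium, field


def test_matches_infinite_medium_greens_function(homogeneous_solution):
    geo, medium, field = homogeneous_solution
    mua, musp = 0.05, 15.0
    d = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(3.0 * mua * (mua + musp))
    c = medium.grid.cells_per_axis // 2
    x = medium.grid.centers()
    for steps in range(8, 24):            # r in [0.52, 1.50] cm
        r = x[c + steps] - x[c]
        analytic = np.exp(-mueff * r) / (4.0 * np.pi * d * r)
        assert field.phi[c + steps, c, c] == pytest.approx(analytic, rel=0.03)


def test_fluence_positive_and_converged(homogeneous_solution):
    _, _, field = homogeneous_solution
    assert field.phi.min() > 0
    assert field.residual < 1e-10 * 1.01


def test_flux_balance(homogeneous_solution):
    geo, medium, field = homogeneous_solution
    balance = fl.flux_balance(field, medium)
    assert abs(balance["imbalance"]) < 0.005
    assert balance["absorbed"] > 0 and balance["boundary_outflux"] > 0


def test_absorber_voxel_count_default(default_geometry):
    medium = fl.build_medium(default_geometry, musp_percm=10.0)
    mask = fl.absorber_mask(medium.grid, default_geometry)
    assert int(mask.sum()) == 20**3
    assert np.all(medium.mua[mask] == 0.5)
    assert np.all(medium.mua[~mask] == 0.05)


def test_absorber_mean_of_constant_field(coarse_geometry):
    medium = fl.build_medium(coarse_geometry, musp_percm=10.0)
    field = fl.FluenceField(
        grid=medium.grid, phi=np.full(medium.mua.shape, 3.25),
        source_position_cm=(0.0, 2.6, 2.6), source_voxel=(0, 13, 13),
        iterations=0, residual=0.0,
    )
    assert fl.absorber_mean(field, coarse_geometry) == pytest.approx(3.25)


@pytest.fixture(scope="module")
def coarse_solution(coarse_geometry):
    medium = fl.build_medium(coarse_geometry, musp_percm=10.0)
    field = fl.solve_pde(medium, coarse_geometry, SolverOptions())
    return medium, field


def test_source_linearity(coarse_geometry, coarse_solution):
    medium, field = coarse_solution
    double = fl.solve_pde(medium, coarse_geometry, SolverOptions(), source_power=2.0)
    assert np.allclose(double.phi, 2.0 * field.phi, rtol=1e-8)


def test_solver_deterministic(coarse_geometry, coarse_solution):
    medium, field = coarse_solution
    again = fl.solve_pde(medium, coarse_geometry, SolverOptions())
    assert np.array_equal(again.phi, field.phi)


def test_line_profile_shape_and_decay(coarse_geometry, coarse_solution):
    medium, field = coarse_solution
    profile = fl.line_profile(field, y_cm=2.6, z_cm=2.6)
    assert len(profile) == medium.grid.cells_per_axis
    assert set(profile.columns) == {"x_cm", "distance_cm", "phi"}
    # monotone diffusive decay beyond the buried source, absorber aside
    phi = profile["phi"].to_numpy()
    start = field.source_voxel[0] + 1
    assert np.all(np.diff(phi[start:]) < 0)


def test_line_profile_outside_grid_rejected(coarse_solution):
    _, field = coarse_solution
    with pytest.raises(ValueError):
        fl.line_profile(field, y_cm=99.0, z_cm=2.6)


def test_phi_a_decreases_with_scattering(coarse_geometry):
    """Stronger scattering shields the central absorber."""
    means = []
    for musp in (5.0, 10.0, 20.0):
        medium = fl.build_medium(coarse_geometry, musp_percm=musp)
        field = fl.solve_pde(medium, coarse_geometry, SolverOptions())
        means.append(fl.absorber_mean(field, coarse_geometry))
    assert means[0] > means[1] > means[2]


def test_alumina_decays_faster_than_silica(silica, alumina, medium_geometry):
    """At equal volume fraction the alumina suspension scatters more
    strongly, so its fluence decays faster along the source axis."""
    profiles = {}
    for spec in (silica, alumina):
        musp = scattering_properties(0.15, spec, "DST").musp_percm
        medium = fl.build_medium(medium_geometry, musp)
        field = fl.solve_pde(medium, medium_geometry, SolverOptions())
        profiles[spec.name] = fl.line_profile(field, 2.6, 2.6)["phi"].to_numpy()
    n = medium_geometry.cells_per_axis
    ratio = profiles["alumina"] / profiles["silica"]
    # normalized to the entry region, alumina falls below silica with depth
    assert ratio[n // 2] / ratio[5] < 0.1


def test_dst_ist_fluence_ratio_near_unity_in_dilute_limit(silica, medium_geometry):
    fields = {}
    for theory in ("IST", "DST"):
        musp = scattering_properties(0.01, silica, theory).musp_percm
        medium = fl.build_medium(medium_geometry, musp)
        fields[theory] = fl.solve_pde(medium, medium_geometry, SolverOptions())
    ratio = fields["DST"].phi / fields["IST"].phi
    assert np.all(np.abs(ratio - 1.0) < 0.25)


def test_grid_refinement_consistency(silica):
    """Refining the grid 3x changes the absorber-mean fluence by < 2%.

    Run on a reduced cube with an odd refinement factor so that the buried
    source and the absorber boundaries fall on voxel centers of both grids
    (cell-centered grids at h and h/2 share no centers)."""
    means = {}
    for h in (0.12, 0.04):
        geo = MediumGeometry(
            cube_side_cm=2.4, grid_spacing_cm=h, absorber_side_cm=0.72,
            absorber_center_cm=(1.2, 1.2, 1.2),
            source_position_cm=(0.0, 1.14, 1.14),
        )
        medium = fl.build_medium(geo, musp_percm=1.0 / 0.18)
        field = fl.solve_pde(medium, geo, SolverOptions())
        means[h] = fl.absorber_mean(field, geo)
    assert means[0.04] == pytest.approx(means[0.12], rel=0.02)


def test_save_field_round_trip(tmp_path, coarse_geometry, coarse_solution):
    import h5py

    medium, field = coarse_solution
    path = tmp_path / "field.h5"
    fl.save_field(path, field, medium, eta=0.1, theory="DST")
    with h5py.File(path) as fh:
        assert np.array_equal(fh["phi"][...], field.phi)
        assert fh.attrs["h_cm"] == medium.grid.spacing_cm
        assert fh.attrs["theory"] == "DST"
    assert (tmp_path / "field.h5.json").exists()
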