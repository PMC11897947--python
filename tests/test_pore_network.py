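"""Watershed separation, pore statistics, ellipsoid model and PNM flow."""

import math

import numpy as np
import pytest

from conftest import ball_mask
from porespec import (
    BinaryMask,
    EllipsoidModel,
    PoreNetwork,
    component_stats,
    ellipsoid_volume,
    extract_network,
    pnm_mass_balance,
    pnm_solve,
    watershed_separate,
)

H_M = 7.5e-6  # voxel edge in m
VOX_MM = 7.5e-3


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------

def test_two_overlapping_spheres_separate_into_two_pores():
    r = 8
    d = int(round(1.8 * r))  # interpenetration of 20% of the radius
    zz, yy, xx = np.indices((40, 24, 24))
    b1 = (zz - 10) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= r * r
    b2 = (zz - 10 - d) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= r * r
    pore = BinaryMask(b1 | b2, 7.5, "pore")
    labeled = watershed_separate(pore)
    assert labeled.n_labels == 2
    vols = np.bincount(labeled.labels.ravel())[1:]
    for v in vols:
        assert v == pytest.approx(b1.sum(), rel=0.10)
    # conservation: every pore voxel is labeled
    assert vols.sum() == pore.voxel_count


def test_single_convex_pore_is_one_label():
    pore = ball_mask((20, 20, 20), (10, 10, 10), 6, role="pore")
    assert watershed_separate(pore).n_labels == 1


def test_watershed_conserves_voxels_on_random_mask(rng):
    from scipy import ndimage

    mask = ndimage.binary_dilation(rng.random((24, 24, 24)) < 0.05, iterations=3)
    pore = BinaryMask(mask, 7.5, "pore")
    labeled = watershed_separate(pore)
    assert (labeled.labels > 0).sum() == pore.voxel_count
    assert set(np.unique(labeled.labels)) == set(range(labeled.n_labels + 1))


def test_watershed_rejects_empty_mask():
    with pytest.raises(ValueError):
        watershed_separate(BinaryMask(np.zeros((4, 4, 4), bool), 7.5, "pore"))


# ---------------------------------------------------------------------------
# per-pore statistics
# ---------------------------------------------------------------------------

def test_sphere_stats_volume_and_aspect():
    pore = ball_mask((26, 26, 26), (13, 13, 13), 10, role="pore")
    labeled = watershed_separate(pore)
    table = component_stats(labeled)
    assert len(table) == 1
    v_analytic = (4.0 / 3.0) * math.pi * (10 * VOX_MM) ** 3
    assert table.volume_mm3[0] == pytest.approx(v_analytic, rel=0.05)
    assert table.aspect_ratio[0] == pytest.approx(1.0, abs=0.05)
    assert table.eq_diameter_mm[0] == pytest.approx(2 * 10 * VOX_MM, rel=0.05)


def test_prolate_ellipsoid_aspect_ratio():
    zz, yy, xx = np.indices((40, 20, 20))
    ell = ((zz - 20) / 16.0) ** 2 + ((yy - 10) / 8.0) ** 2 + ((xx - 10) / 8.0) ** 2 <= 1
    from porespec import LabeledPores

    labeled = LabeledPores(ell.astype(np.int32), 1, 7.5)
    table = component_stats(labeled)
    assert table.aspect_ratio[0] == pytest.approx(0.5, rel=0.10)


def test_stats_volumes_sum_to_mask_volume(rng):
    from scipy import ndimage

    mask = ndimage.binary_dilation(rng.random((24, 24, 24)) < 0.05, iterations=3)
    pore = BinaryMask(mask, 7.5, "pore")
    labeled = watershed_separate(pore)
    table = component_stats(labeled)
    assert table.volume_mm3.sum() == pytest.approx(pore.voxel_count * VOX_MM**3)


# ---------------------------------------------------------------------------
# ellipsoid pore model
# ---------------------------------------------------------------------------

def test_ellipsoid_volume_shape_cases_match_reported_values():
    """Mean pore local thickness 0.04 mm as the minor semi-axis."""
    flattened = EllipsoidModel.flattened(0.04)  # a = b/2 = c/2
    assert flattened.volume_mm3 == pytest.approx(0.0010723, rel=1e-4)
    assert round(flattened.volume_mm3, 3) == 0.001  # printed as 0.0010 mm³
    spherical = EllipsoidModel.spherical_ish(0.04)  # a = b = c/2
    assert spherical.volume_mm3 == pytest.approx(0.0005362, rel=1e-4)
    assert round(spherical.volume_mm3, 4) == 0.0005  # printed as 0.0005 mm³


def test_ellipsoid_volume_sphere_and_errors():
    r = 0.07
    assert ellipsoid_volume(r, r, r) == pytest.approx((4 / 3) * math.pi * r**3)
    with pytest.raises(ValueError):
        ellipsoid_volume(-0.01, 0.04, 0.04)


# ---------------------------------------------------------------------------
# network extraction
# ---------------------------------------------------------------------------

def test_straight_tube_network_throat_radii():
    from porespec import generate_fixture

    pore = generate_fixture("tube", {"radius": 10, "cross": 32, "length": 64})
    labeled = watershed_separate(pore)
    net = extract_network(labeled, pore, "z")
    assert (net.tags == "inlet").sum() == 1 and (net.tags == "outlet").sum() == 1
    assert np.all(np.abs(net.throat_radius / VOX_MM - 10) <= 1.0)
    # throat endpoints are distinct existing pores
    assert np.all(net.throats[:, 0] != net.throats[:, 1])
    assert net.throats.max() < net.n_pores


def test_dumbbell_neck_throat_radius():
    zz, yy, xx = np.indices((64, 32, 32))
    ball1 = (zz - 10) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 145
    ball2 = (zz - 53) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 145
    neck = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 16) & (zz >= 10) & (zz <= 53)
    pore = BinaryMask(ball1 | ball2 | neck, 7.5, "pore")
    labeled = watershed_separate(pore, min_separation=4)
    net = extract_network(labeled, pore, "z")
    internal = (net.tags[net.throats[:, 0]] == "internal") & (
        net.tags[net.throats[:, 1]] == "internal"
    )
    assert internal.sum() >= 1
    np.testing.assert_allclose(net.throat_radius[internal] / VOX_MM, 4.0, atol=1.0)


def test_network_requires_percolation():
    pore = ball_mask((20, 20, 20), (10, 10, 10), 5, role="pore")
    labeled = watershed_separate(pore)
    with pytest.raises(ValueError, match="percolate"):
        extract_network(labeled, pore, "z")


# ---------------------------------------------------------------------------
# PNM solve
# ---------------------------------------------------------------------------

def _single_throat_network(radius_mm=0.05, length_mm=0.4):
    return PoreNetwork(
        centers=np.array([[0.0, 0.0, 0.0], [length_mm, 0.0, 0.0]]),
        radii=np.array([radius_mm, radius_mm]),
        tags=np.array(["inlet", "outlet"], dtype=object),
        throats=np.array([[0, 1]]),
        throat_radius=np.array([radius_mm]),
        throat_length=np.array([length_mm]),
    )


def test_single_throat_flux_is_poiseuille_closed_form():
    r, length, dp, mu = 0.05e-3, 0.4e-3, 1000.0, 0.001
    net = _single_throat_network()
    res, _ = pnm_solve(net, domain_cross_section=1e-6, domain_length=length,
                       axis="z", delta_p=dp, viscosity=mu)
    analytic = math.pi * r**4 * dp / (8.0 * mu * length)
    assert abs(res.total_flux - analytic) / analytic < 1e-6
    assert res.tortuosity == pytest.approx(1.0)


def test_two_equal_throats_in_series_halve_the_flux():
    r, length = 0.05, 0.4
    net2 = PoreNetwork(
        centers=np.array([[0, 0, 0], [length, 0, 0], [2 * length, 0, 0.0]]),
        radii=np.array([r, r, r]),
        tags=np.array(["inlet", "internal", "outlet"], dtype=object),
        throats=np.array([[0, 1], [1, 2]]),
        throat_radius=np.array([r, r]),
        throat_length=np.array([length, length]),
    )
    res1, _ = pnm_solve(_single_throat_network(), 1e-6, length * 1e-3, axis="z")
    res2, _ = pnm_solve(net2, 1e-6, 2 * length * 1e-3, axis="z")
    assert res2.total_flux == pytest.approx(res1.total_flux / 2.0, rel=1e-12)


def test_doubling_delta_p_doubles_flux_leaves_k():
    net = _single_throat_network()
    r1, _ = pnm_solve(net, 1e-6, 4e-4, axis="z", delta_p=1000.0)
    r2, _ = pnm_solve(net, 1e-6, 4e-4, axis="z", delta_p=2000.0)
    assert r2.total_flux == pytest.approx(2 * r1.total_flux)
    assert r2.k_m2 == pytest.approx(r1.k_m2)


def test_mass_balance_and_relabeling_invariance():
    rng = np.random.default_rng(5)
    # random ladder network between inlet and outlet
    n_int = 6
    centers = np.zeros((n_int + 2, 3))
    centers[:, 0] = np.linspace(0, 1.0, n_int + 2)
    centers[:, 1] = rng.uniform(-0.1, 0.1, n_int + 2)
    tags = np.array(["inlet"] + ["internal"] * n_int + ["outlet"], dtype=object)
    throats = np.array([[i, i + 1] for i in range(n_int + 1)] + [[1, 3], [2, 5]])
    t_r = rng.uniform(0.02, 0.05, len(throats))
    t_l = rng.uniform(0.1, 0.3, len(throats))
    net = PoreNetwork(centers, np.full(n_int + 2, 0.05), tags, throats, t_r, t_l)
    res, pressures = pnm_solve(net, 1e-6, 1e-3, axis="z")
    assert pnm_mass_balance(net, pressures, res.viscosity) <= 1e-10

    perm = rng.permutation(n_int + 2)
    inv = np.argsort(perm)
    net_p = PoreNetwork(centers[perm], np.full(n_int + 2, 0.05), tags[perm],
                        inv[throats], t_r, t_l)
    res_p, _ = pnm_solve(net_p, 1e-6, 1e-3, axis="z")
    assert res_p.k_m2 == pytest.approx(res.k_m2, rel=1e-10)
    assert res_p.tortuosity == pytest.approx(res.tortuosity, rel=1e-10)


def test_axial_network_tortuosity_is_exactly_one():
    net = PoreNetwork(
        centers=np.array([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0.0]]),
        radii=np.array([0.05, 0.05, 0.05]),
        tags=np.array(["inlet", "internal", "outlet"], dtype=object),
        throats=np.array([[0, 1], [1, 2]]),
        throat_radius=np.array([0.04, 0.03]),
        throat_length=np.array([0.3, 0.3]),
    )
    res, _ = pnm_solve(net, 1e-6, 6e-4, axis="z")
    assert res.tortuosity == 1.0


def test_isolated_internal_pore_is_singular():
    net = PoreNetwork(
        centers=np.array([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0], [0.3, 0.3, 0.0]]),
        radii=np.full(4, 0.05),
        tags=np.array(["inlet", "internal", "outlet", "internal"], dtype=object),
        throats=np.array([[0, 1], [1, 2]]),
        throat_radius=np.array([0.04, 0.04]),
        throat_length=np.array([0.3, 0.3]),
    )
    with pytest.raises(ValueError, match="pore 3"):
        pnm_solve(net, 1e-6, 6e-4, axis="z")


def test_pnm_tube_fixture_matches_analytic_within_discretization():
    from porespec import fixture_analytics, generate_fixture

    pore = generate_fixture("tube", {"radius": 10, "cross": 32, "length": 64})
    labeled = watershed_separate(pore)
    net = extract_network(labeled, pore, "z")
    res, _ = pnm_solve(
        net, domain_cross_section=32 * 32 * H_M * H_M, domain_length=64 * H_M, axis="z"
    )
    analytic = fixture_analytics("tube", {"radius": 10, "cross": 32, "length": 64})
    assert res.k_m2 == pytest.approx(analytic["k_m2"], rel=0.15)


def test_permeability_result_unit_coupling():
    res, _ = pnm_solve(_single_throat_network(), 1e-6, 4e-4, axis="z")
    assert res.k_darcy == pytest.approx(res.k_m2 / 9.869233e-13)
    assert res.k_m2 > 0 and res.tortuosity >= 1.0
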