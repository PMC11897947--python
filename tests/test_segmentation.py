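"""Mask algebra, porosity definition and percolation filtering."""

import numpy as np
import pytest

from conftest import ball_mask
from porespec import (
    BinaryMask,
    SegmentationParams,
    SyntheticSpec,
    VoxelVolume,
    closed_filled_mask,
    generate_sintered_packing,
    percolating_pore_space,
    pore_space,
    porosity_percent,
    segment_volume,
    threshold_material,
)


def test_explicit_threshold_single_voxel():
    data = np.zeros((5, 5, 5), dtype=np.uint8)
    data[2, 2, 2] = 255
    mask = threshold_material(VoxelVolume(data, 7.5), SegmentationParams(threshold=128))
    assert mask.voxel_count == 1 and mask.data[2, 2, 2]


def test_threshold_above_max_warns_and_returns_empty():
    data = np.zeros((4, 4, 4), dtype=np.uint8)
    data[1, 1, 1] = 10
    with pytest.warns(UserWarning, match="empty"):
        mask = threshold_material(VoxelVolume(data, 7.5), SegmentationParams(threshold=200))
    assert mask.voxel_count == 0


def test_otsu_rejects_constant_volume():
    with pytest.raises(ValueError, match="constant"):
        threshold_material(VoxelVolume(np.full((4, 4, 4), 7, np.uint8), 7.5))


def test_otsu_recovers_known_solid_fraction(rng):
    """On a sharply bimodal volume Otsu recovers the true phase split."""
    solid = rng.random((40, 40, 40)) < 0.6
    from scipy import ndimage

    solid = ndimage.binary_closing(solid, np.ones((3, 3, 3)))
    gray = np.where(solid, 220, 30).astype(np.uint8)
    gray = np.clip(gray + rng.normal(0, 8, solid.shape), 0, 255).astype(np.uint8)
    mask = threshold_material(VoxelVolume(gray, 7.5), SegmentationParams())
    assert abs(mask.data.mean() - solid.mean()) < 0.02


def test_keep_largest_component_drops_specks():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data[1:8, 1:8, 1:8] = 200  # big block
    data[9, 9, 9] = 200  # isolated speck
    mask = threshold_material(VoxelVolume(data, 7.5), SegmentationParams(threshold=100))
    assert not mask.data[9, 9, 9]
    assert mask.voxel_count == 7**3


def test_closed_filled_fills_cavity_of_hollow_shell():
    outer = ball_mask((24, 24, 24), (12, 12, 12), 9)
    inner = ball_mask((24, 24, 24), (12, 12, 12), 5)
    shell = BinaryMask(outer.data & ~inner.data, 7.5, "material")
    env = closed_filled_mask(shell, closing_radius=1)
    np.testing.assert_array_equal(env.data, outer.data)


def test_closed_filled_idempotent_on_solid_cube():
    cube = BinaryMask(np.pad(np.ones((6, 6, 6), bool), 4), 7.5, "material")
    env = closed_filled_mask(cube, closing_radius=2)
    np.testing.assert_array_equal(env.data, cube.data)


def test_closed_filled_monotone_in_closing_radius():
    spec = SyntheticSpec(domain_shape=(40, 40, 40), seed=5)
    vol = generate_sintered_packing(spec)
    material = threshold_material(vol)
    prev = 0
    for radius in (0, 1, 2, 3):
        count = closed_filled_mask(material, radius).voxel_count
        assert count >= prev
        prev = count


def test_mask_algebra_identities_on_packing():
    vol = generate_sintered_packing(SyntheticSpec(domain_shape=(40, 40, 40), seed=2))
    material, env, pore = segment_volume(vol)
    assert env.voxel_count >= material.voxel_count
    assert not np.any(pore.data & material.data)
    np.testing.assert_array_equal(pore.data | material.data, env.data)
    assert pore.voxel_count == env.voxel_count - material.voxel_count


def test_pore_space_requires_subset():
    material = ball_mask((10, 10, 10), (5, 5, 5), 4, role="material")
    env = ball_mask((10, 10, 10), (5, 5, 5), 3, role="closed_filled")
    with pytest.raises(ValueError, match="subset"):
        pore_space(material, env)


def test_porosity_percent_definition_and_degenerate_cases():
    env = BinaryMask(np.zeros((5, 5, 5), bool), 7.5, "closed_filled")
    env.data[:4, :5, :5] = True  # 100 voxels
    pore = BinaryMask(np.zeros((5, 5, 5), bool), 7.5, "pore")
    pore.data[:4, :5, :1] = False
    pore.data.flat[np.flatnonzero(env.data)[:44]] = True
    assert porosity_percent(pore, env) == pytest.approx(44.0)
    solid_pore = BinaryMask(np.zeros((5, 5, 5), bool), 7.5, "pore")
    assert porosity_percent(solid_pore, env) == 0.0
    with pytest.raises(ValueError):
        porosity_percent(pore, BinaryMask(np.zeros((5, 5, 5), bool), 7.5, "closed_filled"))


def test_porosity_invariant_under_rotation():
    vol = generate_sintered_packing(SyntheticSpec(domain_shape=(40, 40, 40), seed=4))
    _, env, pore = segment_volume(vol)
    phi = porosity_percent(pore, env)
    rot_pore = BinaryMask(np.rot90(pore.data, axes=(1, 2)).copy(), 7.5, "pore")
    rot_env = BinaryMask(np.rot90(env.data, axes=(1, 2)).copy(), 7.5, "closed_filled")
    assert porosity_percent(rot_pore, rot_env) == pytest.approx(phi)


def test_percolation_keeps_tube_drops_bubble():
    tube = np.zeros((20, 12, 12), dtype=bool)
    tube[:, 5:8, 5:8] = True
    bubble = np.zeros_like(tube)
    bubble[8:11, 1:3, 1:3] = True
    pore = BinaryMask(tube | bubble, 7.5, "pore")
    kept = percolating_pore_space(pore, "z")
    np.testing.assert_array_equal(kept.data, tube)


def test_percolation_error_when_nothing_spans():
    pore = BinaryMask(np.zeros((10, 10, 10), bool), 7.5, "pore")
    pore.data[2:5, 2:5, 2:5] = True
    with pytest.raises(ValueError, match="percolates"):
        percolating_pore_space(pore, "z")


def test_percolation_retains_most_pore_space_in_packing():
    vol = generate_sintered_packing(SyntheticSpec(domain_shape=(48, 48, 48), seed=6))
    _, _, pore = segment_volume(vol)
    core = BinaryMask(pore.data[4:-4, 4:-4, 4:-4].copy(), 7.5, "pore")
    kept = percolating_pore_space(core, "z")
    retained = kept.voxel_count / core.voxel_count
    assert retained > 0
    assert retained >= 0.9  # typical for a ~44%-porosity interconnected matrix
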