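"""Feature-engine tests: census, degenerate contracts, brute-force oracle
equivalence of every texture matrix, and grid invariances."""

import numpy as np
import pytest

from noduleomics import (
    DiscretizationConfig,
    FAMILY_FEATURES,
    ImageVolume,
    N_FEATURES,
    RoiMask,
    extract_case,
    extract_features,
    feature_names,
    gldm_dependence_entropy,
    gldm_dnn,
    glcm_correlation,
    sphericity,
    texture_matrices,
)
from noduleomics.radiomics_engine import (
    _glcm_features_one,
    discretize,
    mesh_volume_area,
    unique_directions,
)

from conftest import ball_mask, make_roi, make_volume
import oracles


def random_roi_volume(rng, shape=(5, 5, 5), n_levels=4, p_roi=0.7):
    """Integer-valued toy volume with a random ROI (bin width 1)."""
    vox = rng.integers(1, n_levels + 1, size=shape).astype(float)
    mask = rng.random(shape) < p_roi
    if not mask.any():
        mask[0, 0, 0] = True
    vol = ImageVolume(voxels=vox, spacing_mm=(1, 1, 1))
    return vol, RoiMask(voxels=mask), int(vox[mask].max() - vox[mask].min() + 1)


def roi_levels(vol, roi):
    """The level array the engine should see (bin width 1, integer data)."""
    lev = np.zeros(vol.shape, dtype=int)
    vals = vol.voxels[roi.voxels]
    lev[roi.voxels] = (vol.voxels[roi.voxels] - vals.min() + 1).astype(int)
    idx = np.argwhere(roi.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return lev[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def test_feature_census_and_families(rng, unit_cfg):
    assert N_FEATURES == 107
    counts = {fam: len(v) for fam, v in FAMILY_FEATURES.items()}
    assert counts == {
        "shape": 14, "firstorder": 18, "glcm": 24,
        "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5,
    }
    vol, roi, _ = random_roi_volume(rng, shape=(6, 6, 4))
    feats = extract_features(vol, roi, unit_cfg)
    assert set(feats) == set(feature_names(role="intra"))
    assert all(np.isfinite(v) for v in feats.values())


def test_intra_plus_peri_extraction_gives_214(rng, unit_cfg):
    vol, roi, _ = random_roi_volume(rng, shape=(7, 7, 5))
    peri = RoiMask(voxels=~roi.voxels, role="peri")
    feats = extract_case(vol, roi, peri, unit_cfg)
    assert len(feats) == 214
    assert sum(k.endswith("_intra") for k in feats) == 107
    assert sum(k.endswith("_peri") for k in feats) == 107


# ---------------------------------------------------------------------------
# Degenerate contracts
# ---------------------------------------------------------------------------

def test_constant_roi_firstorder_and_glcm_limits(unit_cfg):
    vol = make_volume(np.full((4, 4, 3), 7.0))
    roi = make_roi(vol)
    feats = extract_features(vol, roi, unit_cfg)
    assert feats["firstorder_Variance_intra"] == 0.0
    assert feats["firstorder_Entropy_intra"] == 0.0
    assert feats["firstorder_Uniformity_intra"] == 1.0
    assert feats["glcm_Correlation_intra"] == 1.0  # degenerate contract


def test_empty_roi_rejected(unit_cfg):
    vol = make_volume(np.zeros((3, 3, 3)))
    roi = RoiMask(voxels=np.zeros((3, 3, 3), dtype=bool))
    with pytest.raises(ValueError, match="empty"):
        extract_features(vol, roi, unit_cfg)


def test_single_voxel_roi_uses_degenerate_contract(unit_cfg):
    vol = make_volume(np.arange(27, dtype=float).reshape(3, 3, 3))
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    feats = extract_features(vol, RoiMask(voxels=mask), unit_cfg)
    assert all(np.isfinite(v) for v in feats.values())
    tm = texture_matrices(vol, RoiMask(voxels=mask), unit_cfg)
    assert gldm_dependence_entropy(tm) == 0.0
    assert gldm_dnn(tm) == 1.0


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence (criterion-level check lives in
# test_acceptance; here per matrix with several random ROIs)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_texture_matrices_match_bruteforce(seed, unit_cfg):
    rng = np.random.default_rng(seed)
    vol, roi, _ = random_roi_volume(rng, shape=(5, 4, 5))
    tm = texture_matrices(vol, roi, unit_cfg)
    lev = roi_levels(vol, roi)
    ng = tm.n_levels
    for d in unique_directions():
        np.testing.assert_array_equal(tm.glcm[d], oracles.bf_glcm(lev, d, ng))
        np.testing.assert_array_equal(tm.glrlm[d], oracles.bf_glrlm(lev, d, ng))
    np.testing.assert_array_equal(tm.glszm, oracles.bf_glszm(lev, ng))
    np.testing.assert_array_equal(tm.gldm, oracles.bf_gldm(lev, ng))
    n, s = oracles.bf_ngtdm(lev, ng)
    np.testing.assert_array_equal(tm.ngtdm_n, n)
    np.testing.assert_allclose(tm.ngtdm_s, s, atol=1e-12)


def test_toy_pattern_glcm_gldm_match_bruteforce(unit_cfg):
    # hand-written 4x4x1 intensity pattern
    pattern = [[1, 2, 2, 3], [3, 2, 1, 1], [4, 4, 2, 2], [1, 3, 3, 4]]
    vol = make_volume(pattern)
    roi = make_roi(vol)
    tm = texture_matrices(vol, roi, unit_cfg)
    lev = np.asarray(pattern)[:, :, None]
    for d in unique_directions():
        np.testing.assert_array_equal(tm.glcm[d], oracles.bf_glcm(lev, d, 4))
    np.testing.assert_array_equal(tm.gldm, oracles.bf_gldm(lev, 4))


def test_gldm_entropy_dnn_match_bruteforce_formulas(unit_cfg):
    pattern = [[1, 2, 1], [2, 2, 2], [1, 2, 3]]
    vol = make_volume(pattern)
    roi = make_roi(vol)
    tm = texture_matrices(vol, roi, unit_cfg)
    bf = oracles.bf_gldm(np.asarray(pattern)[:, :, None], 3).astype(float)
    p = bf / bf.sum()
    ent = -np.sum(p[p > 0] * np.log2(p[p > 0]))
    dnn = np.sum(bf.sum(axis=0) ** 2) / bf.sum() ** 2
    assert gldm_dependence_entropy(tm) == pytest.approx(ent, abs=1e-12)
    assert gldm_dnn(tm) == pytest.approx(dnn, abs=1e-12)


def test_noise_increases_dependence_entropy(unit_cfg):
    base = np.full((6, 6, 4), 10.0)
    vol_const = make_volume(base)
    rng = np.random.default_rng(3)
    vol_noisy = make_volume(base + rng.integers(0, 4, size=base.shape))
    roi = make_roi(vol_const)
    e_const = gldm_dependence_entropy(texture_matrices(vol_const, roi, unit_cfg))
    e_noisy = gldm_dependence_entropy(texture_matrices(vol_noisy, roi, unit_cfg))
    assert e_noisy > e_const


# ---------------------------------------------------------------------------
# GLCM Correlation
# ---------------------------------------------------------------------------

def test_glcm_correlation_checkerboard_matches_bruteforce(unit_cfg):
    g = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1  # 3-D checkerboard
    vol = make_volume(g.astype(float))
    roi = make_roi(vol)
    tm = texture_matrices(vol, roi, unit_cfg)
    lev = g.astype(int)
    expected = np.mean(
        [oracles.bf_glcm_correlation(lev, d, 2) for d in unique_directions()]
    )
    assert glcm_correlation(tm) == pytest.approx(expected, abs=1e-12)


def test_glcm_correlation_near_one_along_constant_axis(unit_cfg):
    # constant along x, random levels across (y, z) planes
    rng = np.random.default_rng(0)
    plane = rng.integers(1, 6, size=(1, 8, 8))
    vol = make_volume(np.repeat(plane, 8, axis=0).astype(float))
    roi = make_roi(vol)
    tm = texture_matrices(vol, roi, unit_cfg)
    feats = _glcm_features_one(tm.glcm[(1, 0, 0)])
    assert feats["Correlation"] > 0.9


# ---------------------------------------------------------------------------
# Shape / sphericity
# ---------------------------------------------------------------------------

def test_single_voxel_mesh_matches_octahedron_closed_form():
    # marching cubes around one voxel yields the regular octahedron with
    # circumradius 1/2: V = 1/6, A = sqrt(3)
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    v, a = mesh_volume_area(RoiMask(voxels=mask), (1.0, 1.0, 1.0))
    assert v == pytest.approx(1.0 / 6.0, abs=1e-6)
    assert a == pytest.approx(np.sqrt(3.0), abs=1e-6)
    expected = (36 * np.pi * v**2) ** (1 / 3) / a
    assert sphericity(RoiMask(voxels=mask), (1, 1, 1)) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(np.pi ** (1 / 3) / np.sqrt(3), abs=1e-6)


def test_ball_sphericity_high_and_increasing_with_radius():
    values = []
    for r in (8, 16):
        n = 2 * r + 5
        roi = RoiMask(voxels=ball_mask((n, n, n), r))
        values.append(sphericity(roi, (1, 1, 1)))
    assert all(0.90 <= v <= 1.0 for v in values)
    assert values[1] > values[0]


def test_discretize_fixed_bin_width():
    x = np.array([-100.0, -76.0, -75.0, 0.0, 24.9, 25.0])
    lev = discretize(x, 25.0)
    # floor(x/25) - floor(-100/25) + 1
    np.testing.assert_array_equal(lev, [1, 1, 2, 5, 5, 6])
    assert lev.min() == 1


# ---------------------------------------------------------------------------
# Invariances
# ---------------------------------------------------------------------------

def test_translation_invariance(rng, unit_cfg):
    vox = rng.integers(0, 5, size=(4, 4, 3)).astype(float)
    big = np.zeros((12, 12, 9))
    mask = np.zeros((12, 12, 9), dtype=bool)
    big[1:5, 1:5, 1:4] = vox
    mask[1:5, 1:5, 1:4] = True
    f1 = extract_features(make_volume(big), RoiMask(voxels=mask), unit_cfg)
    big2 = np.roll(big, (5, 3, 2), axis=(0, 1, 2))
    mask2 = np.roll(mask, (5, 3, 2), axis=(0, 1, 2))
    f2 = extract_features(make_volume(big2), RoiMask(voxels=mask2), unit_cfg)
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-9), k


def test_rotation_90deg_invariance(rng, unit_cfg):
    """Rotating the grid 90 degrees about z (x/y spacing equal) leaves all
    features unchanged except the axis-labelled in-plane diameters, which
    swap with each other."""
    vox = rng.integers(0, 5, size=(6, 5, 4)).astype(float)
    mask = rng.random((6, 5, 4)) < 0.8
    mask[2, 2, 2] = True
    f1 = extract_features(make_volume(vox, spacing=(1, 1, 2.5)),
                          RoiMask(voxels=mask), unit_cfg)
    vox_r = np.rot90(vox, axes=(0, 1)).copy()
    mask_r = np.rot90(mask, axes=(0, 1)).copy()
    f2 = extract_features(make_volume(vox_r, spacing=(1, 1, 2.5)),
                          RoiMask(voxels=mask_r), unit_cfg)
    swap = {
        "shape_Maximum2DDiameterColumn_intra": "shape_Maximum2DDiameterRow_intra",
        "shape_Maximum2DDiameterRow_intra": "shape_Maximum2DDiameterColumn_intra",
    }
    for k in f1:
        assert f1[k] == pytest.approx(f2[swap.get(k, k)], rel=1e-6, abs=1e-9), k
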