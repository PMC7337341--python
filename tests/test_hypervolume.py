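"""One-class SVM hypervolumes: volume oracle, nu-property, geometry, determinism."""

import numpy as np
import pytest

from hyperniche.hypervolume import fit_hypervolume


def grid_volume(hv, n=400):
    """Independent oracle: exhaustive grid integration of the same decision
    function over the hypervolume's own sampling box (2-D only)."""
    assert hv.m == 2
    xs = np.linspace(hv.box_lo[0], hv.box_hi[0], n)
    ys = np.linspace(hv.box_lo[1], hv.box_hi[1], n)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    frac = hv.contains(pts).mean()
    return hv.box_volume * frac


def test_unit_square_volume_against_grid_oracle():
    """1000 uniform points on the unit square: MC volume within the stated
    band and within 3 combined SEs of the grid enumeration oracle."""
    rng = np.random.default_rng(0)
    pts = rng.uniform(size=(1000, 2))
    hv = fit_hypervolume(pts, mc_draws=100_000, seed=1)
    assert 0.8 <= hv.volume <= 1.3
    oracle = grid_volume(hv)
    assert abs(hv.volume - oracle) <= 3 * hv.volume_se + 0.01


def test_nu_property_uniform_square():
    rng = np.random.default_rng(2)
    pts = rng.uniform(size=(1000, 2))
    hv = fit_hypervolume(pts, mc_draws=1000, seed=1)
    frac_out = 1.0 - hv.contains(pts).mean()
    assert frac_out <= 3 * hv.nu


def test_nu_property_across_random_blobs():
    """Across 10 random anisotropic blobs, ≤ 3nu of training points are
    classified outside their own hypervolume."""
    for s in range(10):
        rng = np.random.default_rng(s)
        m = int(rng.integers(2, 5))
        pts = rng.normal(size=(300, m)) * rng.uniform(0.5, 4.0, size=m)
        hv = fit_hypervolume(pts, mc_draws=2000, seed=s)
        assert 1.0 - hv.contains(pts).mean() <= 3 * hv.nu


def test_determinism_under_fixed_seed():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(200, 3))
    a = fit_hypervolume(pts, mc_draws=20_000, seed=99)
    b = fit_hypervolume(pts.copy(), mc_draws=20_000, seed=99)
    assert a.volume == b.volume
    np.testing.assert_array_equal(a.centroid, b.centroid)
    np.testing.assert_array_equal(a.inliers, b.inliers)


def test_centroid_of_symmetric_blob_near_origin():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(2000, 2))
    hv = fit_hypervolume(pts, mc_draws=50_000, seed=3)
    se = (hv.box_hi - hv.box_lo) / np.sqrt(12 * len(hv.inliers))
    assert np.all(np.abs(hv.centroid) <= 5 * se + 0.05)


def test_centroid_translation_equivariance():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(500, 2))
    v = np.array([10.0, -7.0])
    a = fit_hypervolume(pts, mc_draws=30_000, seed=8)
    b = fit_hypervolume(pts + v, mc_draws=30_000, seed=8)
    np.testing.assert_allclose(b.centroid - a.centroid, v, atol=0.1)


def test_axis_extent_of_known_span():
    """Points spanning [-1, 1] on axis 0 give extent length ≈ 2 (MC + boundary
    smoothing tolerance)."""
    rng = np.random.default_rng(7)
    pts = np.column_stack([rng.uniform(-1, 1, 1500), rng.uniform(-0.5, 0.5, 1500)])
    hv = fit_hypervolume(pts, mc_draws=50_000, seed=2)
    lo, hi = hv.axis_extent(0)
    assert abs((hi - lo) - 2.0) < 0.45


def test_extent_grows_by_cluster_separation():
    rng = np.random.default_rng(8)
    one = rng.normal(size=(400, 2)) * 0.3
    two = np.vstack([one, one + np.array([8.0, 0.0])])
    a = fit_hypervolume(one, mc_draws=20_000, seed=5)
    b = fit_hypervolume(two, mc_draws=20_000, seed=5)
    la = a.axis_extent(0)[1] - a.axis_extent(0)[0]
    lb = b.axis_extent(0)[1] - b.axis_extent(0)[0]
    assert abs((lb - la) - 8.0) < 1.0


def test_volume_scaling_in_2d():
    """Doubling coordinates (gamma/4 to preserve shape) scales area by ≈4."""
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(600, 2))
    a = fit_hypervolume(pts, gamma=0.5, mc_draws=50_000, seed=6)
    b = fit_hypervolume(2 * pts, gamma=0.125, mc_draws=50_000, seed=6)
    assert abs(b.volume / a.volume - 4.0) < 0.4


def test_far_point_not_contained():
    rng = np.random.default_rng(10)
    pts = rng.normal(size=(200, 2))
    hv = fit_hypervolume(pts, mc_draws=1000, seed=1)
    span = hv.box_hi - hv.box_lo
    assert not hv.contains((hv.box_hi + 100 * span)[None, :])[0]


def test_input_validation():
    rng = np.random.default_rng(11)
    with pytest.raises(ValueError, match="records"):
        fit_hypervolume(rng.normal(size=(5, 2)))
    flat = np.column_stack([np.ones(50), rng.normal(size=50)])
    with pytest.raises(ValueError, match="degenerate"):
        fit_hypervolume(flat)
    with pytest.raises(ValueError):
        fit_hypervolume(rng.normal(size=(50, 2)), gamma=-1)
    with pytest.raises(ValueError):
        fit_hypervolume(rng.normal(size=(50, 2)), nu=1.5)


def test_json_roundtrip_reproduces_volume(tmp_path):
    from hyperniche.hypervolume import NicheHypervolume

    rng = np.random.default_rng(12)
    pts = rng.normal(size=(150, 2))
    hv = fit_hypervolume(pts, mc_draws=10_000, seed=13, label="t")
    hv.to_json(tmp_path / "hv.json")
    back = NicheHypervolume.from_json(tmp_path / "hv.json")
    assert back.volume == hv.volume
    np.testing.assert_array_equal(back.centroid, hv.centroid)
    assert back.label == "t"
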