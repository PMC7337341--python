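"""MCP construction, pseudo-absence sampling, and the True Skill Statistic."""

import numpy as np
import pytest
from scipy.stats import chisquare

from hyperniche.evaluation import (
    ConfusionMatrix,
    minimum_convex_polygon,
    pseudo_absences,
    scaled_n_random,
    tss,
    tss_from_confusion,
)
from hyperniche.geoprojection import SuitabilityRaster
from hyperniche.rasters import ClimateStack, GridSpec

from conftest import make_occ


class TestMCP:
    def test_triangle_through_three_points(self):
        mcp = minimum_convex_polygon(make_occ([(0, 0, 1950), (4, 0, 1950), (0, 3, 1950)]))
        assert len(mcp.polygon.exterior.coords) == 4  # closed ring
        assert mcp.contains_points(np.array([1.0]), np.array([1.0]))[0]

    def test_interior_point_dropped_from_hull(self):
        mcp = minimum_convex_polygon(
            make_occ([(0, 0, 1950), (4, 0, 1950), (0, 4, 1950), (1, 1, 1950)])
        )
        assert len(mcp.polygon.exterior.coords) == 4  # triangle, not quad

    def test_dateline_recentre_shrinks_span(self):
        """Points at lon 170 and −170 hull across the dateline (20°, not 340°)."""
        mcp = minimum_convex_polygon(
            make_occ([(170, 0, 1950), (-170, 0, 1950), (175, 5, 1950)])
        )
        assert mcp.shifted
        xs = mcp.polygon.exterior.xy[0]
        assert max(xs) - min(xs) == pytest.approx(20.0)
        # membership works with either sign convention of the query longitude
        # (-174, 1) shifts to (186, 1), inside the hull of (170,0),(190,0),(175,5)
        assert mcp.contains_points(np.array([-174.0]), np.array([1.0]))[0]

    def test_collinear_points_error(self):
        with pytest.raises(ValueError):
            minimum_convex_polygon(make_occ([(0, 0, 1950), (1, 1, 1950), (2, 2, 1950)]))

    def test_area_positive_and_scales(self):
        small = minimum_convex_polygon(make_occ([(0, 0, 1950), (1, 0, 1950), (0, 1, 1950)]))
        big = minimum_convex_polygon(make_occ([(0, 0, 1950), (10, 0, 1950), (0, 10, 1950)]))
        assert 0 < small.area_km2 < big.area_km2


def flat_stack(nrows, ncols):
    grid = GridSpec(nrows, ncols, 0, 0, 1.0)
    rng = np.random.default_rng(0)
    data = np.stack([rng.normal(size=(nrows, ncols)) for _ in range(2)])
    return ClimateStack(data, ["a", "b"], grid)


class TestPseudoAbsences:
    def test_points_inside_polygon_and_valid(self):
        stack = flat_stack(6, 6)
        mcp = minimum_convex_polygon(make_occ([(0, 0, 1950), (6, 0, 1950), (0, 6, 1950)]))
        pts = pseudo_absences(mcp, 200, stack, seed=1)
        assert pts.shape == (200, 2)
        assert mcp.contains_points(pts[:, 0], pts[:, 1]).all()

    def test_single_valid_cell_returns_its_center(self):
        grid = GridSpec(2, 2, 0, 0, 1.0)
        data = np.full((2, 2, 2), np.nan)
        data[:, 0, 0] = 1.0  # only the NW cell valid
        stack = ClimateStack(data, ["a", "b"], grid)
        mcp = minimum_convex_polygon(make_occ([(0, 0, 1950), (2, 0, 1950), (0, 2, 1950), (2, 2, 1950)]))
        pts = pseudo_absences(mcp, 1, stack, seed=5)
        np.testing.assert_allclose(pts, [[0.5, 1.5]])

    def test_reproducible_under_seed(self):
        stack = flat_stack(5, 5)
        mcp = minimum_convex_polygon(make_occ([(0, 0, 1950), (5, 0, 1950), (0, 5, 1950)]))
        a = pseudo_absences(mcp, 50, stack, seed=7)
        b = pseudo_absences(mcp, 50, stack, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_uniform_over_cells_chi2(self):
        """Across 10 seeds, draws are uniform over a 10-cell strip (α=0.01)."""
        stack = flat_stack(1, 10)
        mcp = minimum_convex_polygon(
            make_occ([(0, 0, 1950), (10, 0, 1950), (10, 1, 1950), (0, 1, 1950)])
        )
        counts = np.zeros(10)
        for seed in range(10):
            pts = pseudo_absences(mcp, 500, stack, seed=seed)
            cols = np.floor(pts[:, 0]).astype(int)
            counts += np.bincount(cols, minlength=10)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_empty_mcp_error(self):
        grid = GridSpec(2, 2, 0, 0, 1.0)
        data = np.ones((2, 2, 2))
        stack = ClimateStack(data, ["a", "b"], grid)
        mcp = minimum_convex_polygon(
            make_occ([(50, 50, 1950), (51, 50, 1950), (50, 51, 1950)])
        )
        with pytest.raises(ValueError, match="no valid cells"):
            pseudo_absences(mcp, 10, stack, seed=0)


class TestScaledN:
    def test_reference_gets_n_ref(self):
        assert scaled_n_random(1000.0, 1000.0) == 5000

    def test_half_area_half_n(self):
        assert scaled_n_random(500.0, 1000.0) == 2500

    def test_floor_applied(self):
        assert scaled_n_random(1.0, 1000.0) == 100


class TestTSS:
    def make_raster(self, pattern):
        return SuitabilityRaster(np.asarray(pattern, np.uint8), GridSpec(2, 2, 0, 0, 1.0))

    def test_perfect_classifier(self):
        r = self.make_raster([[1, 1], [0, 0]])  # north suitable, south not
        presences = make_occ([(0.5, 1.5, 1950), (1.5, 1.5, 1950)])
        absences = np.array([[0.5, 0.5], [1.5, 0.5]])
        res = tss(r, presences, absences)
        assert res.tss == pytest.approx(1.0)

    def test_everything_suitable_scores_zero(self):
        r = self.make_raster([[1, 1], [1, 1]])
        presences = make_occ([(0.5, 1.5, 1950)])
        absences = np.array([[0.5, 0.5], [1.5, 0.5]])
        res = tss(r, presences, absences)
        assert res.sensitivity == 1.0 and res.specificity == 0.0
        assert res.tss == pytest.approx(0.0)

    def test_hand_confusion_matrix(self):
        res = tss_from_confusion(ConfusionMatrix(tp=8, fp=3, fn=2, tn=7))
        assert res.tss == pytest.approx(0.5)

    def test_presences_deduplicated_per_cell(self):
        r = self.make_raster([[1, 0], [0, 0]])
        presences = make_occ([(0.2, 1.6, 1950), (0.8, 1.2, 1950)])  # same cell
        absences = np.array([[1.5, 0.5]])
        res = tss(r, presences, absences)
        assert res.confusion.tp == 1 and res.confusion.fn == 0

    def test_prevalence_invariance(self):
        """Replicating the absence set leaves sens/spec/TSS unchanged."""
        base = ConfusionMatrix(tp=8, fp=3, fn=2, tn=7)
        scaled = ConfusionMatrix(tp=8, fp=30, fn=2, tn=70)
        assert tss_from_confusion(base).tss == pytest.approx(tss_from_confusion(scaled).tss)

    def test_conservation_of_evaluable_points(self):
        r = self.make_raster([[1, 0], [0, 1]])
        presences = make_occ([(0.5, 1.5, 1950), (1.5, 0.5, 1950), (1.5, 1.5, 1950)])
        absences = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5]])
        res = tss(r, presences, absences)
        cm = res.confusion
        assert cm.tp + cm.fn == 3  # three distinct presence cells
        assert cm.fp + cm.tn == 3

    def test_no_evaluable_presences_error(self):
        r = self.make_raster([[1, 1], [1, 1]])
        presences = make_occ([(50.0, 50.0, 1950)])  # off the raster
        with pytest.raises(ValueError, match="presences"):
            tss(r, presences, np.array([[0.5, 0.5]]))


def test_mean_tss_on_well_specified_synthetic_niche():
    """Across 10 simulated invasions, the mean TSS of the per-period models
    stays at or above 0.5 (the field regards 0.6-0.7 as fair performance)."""
    from hyperniche.pipeline import analyze
    from hyperniche.synthetic import SyntheticScenario, generate_climate, sample_occurrences

    scores = []
    for seed in range(10):
        scn = SyntheticScenario(seed=seed)
        stack = generate_climate(scn)
        occ = sample_occurrences(scn)
        res = analyze(
            occ, stack, scn.slicing, mc_draws=4000, n_ref=2000,
            seed=seed, with_tss=True, with_overlap=False,
        )
        scores.extend(res["tss"])
    assert np.mean(scores) >= 0.5
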