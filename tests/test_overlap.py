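"""FROA core: fixation-region maps, overlap, Monte-Carlo nulls, MMC, saliency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from froa.geometry import ViewingGeometry
from froa.overlap import (
    ChanceDistribution,
    FroaConfig,
    chance_distribution,
    fixation_region_map,
    make_null_density,
    mmc,
    overlap_percent,
    run_froa,
)
from froa.roi import RoiMask
from froa.saliency import saliency_map


def brute_force_overlap(points, roi, shape, radius_px=0.0):
    """Independent oracle: explicit pixel-set union and intersection."""
    pixels = set()
    h, w = shape
    r = int(np.ceil(radius_px))
    for x, y in points:
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dx * dx + dy * dy <= radius_px * radius_px:
                    px, py = int(x) + dx, int(y) + dy
                    if 0 <= px < w and 0 <= py < h:
                        pixels.add((px, py))
    inter = sum(roi[py, px] for px, py in pixels)
    return 100.0 * inter / len(pixels)


class TestFixationRegionMap:
    def test_single_disk_area(self, geometry):
        fm = fixation_region_map([(400, 400)], geometry, 1.0)
        assert fm.mask.sum() == pytest.approx(np.pi * geometry.px_per_deg**2, rel=0.05)

    def test_duplicate_fixations_are_idempotent(self, geometry):
        a = fixation_region_map([(300, 300)], geometry, 1.0)
        b = fixation_region_map([(300, 300), (300, 300)], geometry, 1.0)
        assert np.array_equal(a.mask, b.mask)
        assert b.n_fixations == 2

    def test_radius_monotonicity(self, geometry):
        small = fixation_region_map([(400, 400)], geometry, 0.5)
        large = fixation_region_map([(400, 400)], geometry, 1.0)
        assert small.mask.sum() < large.mask.sum()

    def test_zero_fixations_rejected(self, geometry):
        with pytest.raises(ValueError):
            fixation_region_map(np.empty((0, 2)), geometry, 1.0)


class TestOverlapPercent:
    def test_subset_gives_100(self, geometry):
        fm = fixation_region_map([(400, 400)], geometry, 1.0)
        assert overlap_percent(fm, np.ones((800, 800), bool)) == 100.0

    def test_disjoint_gives_0(self, geometry):
        fm = fixation_region_map([(100, 100)], geometry, 1.0)
        roi = np.zeros((800, 800), bool)
        roi[600:, 600:] = True
        assert overlap_percent(fm, roi) == 0.0

    def test_half_plane_splits_disk(self, geometry):
        fm = fixation_region_map([(400, 400)], geometry, 1.0)
        roi = np.zeros((800, 800), bool)
        roi[:, :400] = True
        assert overlap_percent(fm, roi) == pytest.approx(50, abs=2)

    def test_empty_fixmap_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_percent(np.zeros((10, 10), bool), np.ones((10, 10), bool))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_point_fixation_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        roi = rng.random((16, 16)) < 0.4
        pts = rng.integers(0, 16, size=(rng.integers(1, 12), 2)).astype(float)
        geo = ViewingGeometry(16, 16.0)
        fm = fixation_region_map(pts, geo, region_radius_deg=0.0)
        assert overlap_percent(fm, roi) == pytest.approx(
            brute_force_overlap(pts, roi, (16, 16)), abs=1e-12
        )


class TestChanceDistribution:
    def test_full_frame_roi_always_100(self, geometry):
        null = make_null_density("uniform_frame", (200, 200))
        cd = chance_distribution(
            5, np.ones((200, 200), bool), null, ViewingGeometry(200, 18.0),
            n_iterations=100, seed=0,
        )
        assert np.all(cd.overlaps == 100.0)
        assert cd.q95 == 100.0

    def test_empty_roi_always_0(self, geometry):
        null = make_null_density("uniform_frame", (200, 200))
        cd = chance_distribution(
            5, np.zeros((200, 200), bool), null, ViewingGeometry(200, 18.0),
            n_iterations=100, seed=0,
        )
        assert np.all(cd.overlaps == 0.0)

    def test_point_fixation_expectation_matches_area_share(self):
        roi = np.zeros((200, 200), bool)
        roi[:100, :100] = True  # 25%
        null = make_null_density("uniform_frame", (200, 200))
        cd = chance_distribution(
            1, roi, null, ViewingGeometry(200, 18.0), region_radius_deg=0.0,
            n_iterations=1000, seed=3,
        )
        assert cd.overlaps.mean() == pytest.approx(25, abs=3)

    def test_seed_changes_q95_only_slightly(self, dumbbell_mask):
        roi = np.zeros((400, 400), bool)
        roi[150:250, 120:280] = True
        null = make_null_density("uniform_object", (400, 400), object_mask=dumbbell_mask)
        geo = ViewingGeometry(400, 18.0)
        q = [
            chance_distribution(12, roi, null, geo, 1.0, 1000, seed=s).q95
            for s in (1, 2)
        ]
        assert abs(q[0] - q[1]) < 2.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="zero mass"):
            make_null_density("uniform_object", (50, 50), object_mask=np.zeros((50, 50)))


class TestMmc:
    def test_mmc_is_overlap_minus_bound(self):
        chance = ChanceDistribution(np.zeros(100), 0.0, 100, "uniform_frame", 0)
        assert mmc(30.0, chance).mmc == 30.0

    def test_mmc_zero_at_the_bound(self):
        chance = ChanceDistribution(np.full(100, 40.0), 40.0, 100, "uniform_frame", 0)
        assert mmc(40.0, chance).mmc == 0.0


class TestSaliency:
    def test_uniform_image_gives_near_uniform_density(self):
        sal = saliency_map(np.full((128, 128), 0.5))
        assert sal.max() / sal.min() < 1.5

    def test_bright_disk_concentrates_mass(self):
        img = np.zeros((200, 200))
        yy, xx = np.mgrid[:200, :200]
        disk = (yy - 100) ** 2 + (xx - 100) ** 2 <= 20**2
        img[disk] = 1.0
        sal = saliency_map(img)
        near = (yy - 100) ** 2 + (xx - 100) ** 2 <= 40**2
        assert sal[near].sum() >= 0.6

    def test_normalised_to_unit_mass(self):
        rng = np.random.default_rng(0)
        sal = saliency_map(rng.random((100, 100)))
        assert sal.sum() == pytest.approx(1.0, abs=1e-9)

    def test_usable_as_null_density(self):
        img = np.zeros((100, 100))
        img[40:60, 40:60] = 1.0
        null = make_null_density("saliency", (100, 100), density_map=saliency_map(img))
        pts = null.sample(np.random.default_rng(0), 500)
        assert pts.shape == (500, 2)
        assert pts.min() >= 0 and pts.max() < 100


@pytest.fixture(scope="module")
def small_run():
    from froa.roi import build_all_models
    from froa.synthetic import (
        ExperimentDesign, GroupSpec, ScanPathConfig, generate_shape, simulate_experiment,
    )

    shape = generate_shape("dumbbell", seed=0)
    models = {"s0": build_all_models(shape.silhouette)}
    design = ExperimentDesign(
        groups=[
            GroupSpec("basic", 6, ScanPathConfig(n_fixations=8, roi_preference=0.8),
                      target_model="concave"),
            GroupSpec("subordinate", 6, ScanPathConfig(n_fixations=8, roi_preference=0.8),
                      target_model="concave"),
        ],
        n_trials=3,
        stimuli={"s0": shape},
    )
    df, _, _, _ = simulate_experiment(design, seed=13)
    return df, {"s0": shape.mask}, models


class TestRunFroa:
    def test_long_table_has_one_row_per_participant_model(self, small_run, geometry):
        df, stimuli, models = small_run
        out = run_froa(df, stimuli, models, geometry, FroaConfig(n_iterations=100, seed=1))
        assert len(out) == 12 * 3
        assert set(out.columns) == {"participant", "group", "model", "mmc"}
        assert out["mmc"].between(-100, 100).all()

    def test_preferred_roi_scores_highest(self, small_run, geometry):
        df, stimuli, models = small_run
        out = run_froa(df, stimuli, models, geometry, FroaConfig(n_iterations=200, seed=1))
        means = out.groupby("model")["mmc"].mean()
        assert means["concave"] > means["convex"]

    def test_missing_roi_model_is_reported(self, small_run, geometry):
        df, stimuli, _ = small_run
        with pytest.raises(ValueError, match="s0"):
            run_froa(df, stimuli, {}, geometry, FroaConfig(n_iterations=100))
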