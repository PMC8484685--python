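"""Generator ground truth: masks, determinism, and the scale of the signal."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from panoptes.synthetic_data import (
    SyntheticSlideSpec,
    generate_cohort,
    generate_slide,
    render_slide,
)
from panoptes.tiling import TileFilterConfig, enumerate_tile_sets, plan_grid


class TestRenderSlide:
    def test_no_margin_no_contaminants_all_tissue(self):
        _, mask = render_slide(SyntheticSlideSpec(seed=0, extent=(640, 640)))
        assert (mask == 1).all()

    def test_same_seed_byte_identical_files(self, tmp_path):
        spec = SyntheticSlideSpec(seed=5, extent=(640, 640), margin_fraction=0.1,
                                  n_contaminants=2)
        a, b = tmp_path / "a.tiff", tmp_path / "b.tiff"
        generate_slide(spec, str(a))
        generate_slide(spec, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a, b = tmp_path / "a.tiff", tmp_path / "b.tiff"
        generate_slide(SyntheticSlideSpec(seed=1, extent=(640, 640)), str(a))
        generate_slide(SyntheticSlideSpec(seed=2, extent=(640, 640)), str(b))
        assert a.read_bytes() != b.read_bytes()

    @pytest.mark.parametrize("frac", [0.1, 0.25])
    def test_margin_fraction_matches_mask_counting(self, frac):
        devs = []
        for seed in range(20):
            _, mask = render_slide(
                SyntheticSlideSpec(seed=seed, extent=(640, 640), margin_fraction=frac)
            )
            devs.append(abs((mask == 0).mean() - frac))
        assert max(devs) <= 0.02

    def test_contaminants_marked_and_dark(self):
        slide, mask = render_slide(
            SyntheticSlideSpec(seed=3, extent=(1196, 1196), n_contaminants=3)
        )
        arr = slide.level_array(0)
        assert (mask == 2).any()
        assert np.all(arr[mask == 2] < 50)

    def test_margin_is_white(self):
        slide, mask = render_slide(
            SyntheticSlideSpec(seed=3, extent=(640, 640), margin_fraction=0.2)
        )
        arr = slide.level_array(0)
        assert np.all(arr[mask == 0] > 200)

    def test_pyramid_levels_are_area_averages(self):
        slide, _ = render_slide(SyntheticSlideSpec(seed=4, extent=(640, 640)))
        lvl0 = slide.level_array(0).astype(float)
        lvl1 = slide.level_array(1).astype(float)
        oracle = lvl0.reshape(320, 2, 320, 2, 3).mean(axis=(1, 3))
        assert np.abs(lvl1 - oracle).max() <= 0.51  # rounding only

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSlideSpec(seed=0, extent=(641, 640))
        with pytest.raises(ValueError):
            SyntheticSlideSpec(seed=0, effect=-1)
        with pytest.raises(ValueError):
            SyntheticSlideSpec(seed=0, signal_scale="meso")


class TestGenerateCohort:
    def test_class_balance(self):
        _, labels = generate_cohort(20, class_balance=0.5, seed=0)
        assert labels["subtype"].sum() == 10

    def test_labels_constant_across_patient_slides(self):
        specs, labels = generate_cohort(8, slides_per_patient=3, seed=1)
        assert labels.groupby("patient_id")["subtype"].nunique().max() == 1
        assert len(specs) == 24

    def test_schema_and_cohorts(self):
        _, labels = generate_cohort(16, seed=2, cohort_b_fraction=0.25)
        assert set(labels.columns) == {"patient_id", "slide_id", "cohort",
                                       "subtype", "age", "bmi"}
        assert (labels["cohort"] == "B").sum() == 4
        # cohort B stratified across classes
        b = labels[labels["cohort"] == "B"]
        assert b["subtype"].nunique() == 2

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            generate_cohort(3)

    def test_clinical_shift_moves_class_means(self):
        _, labels = generate_cohort(60, seed=3, clinical_shift=1.5)
        pos = labels[labels["subtype"] == 1]
        neg = labels[labels["subtype"] == 0]
        assert pos["age"].mean() > neg["age"].mean()
        assert pos["bmi"].mean() > neg["bmi"].mean()


class TestSignalScale:
    """The property that makes the multi-resolution claim testable."""

    @pytest.fixture(scope="class")
    def tile_stats(self):
        cfg = TileFilterConfig()
        stats = {0: {"m10": [], "s10": [], "adj25": []},
                 1: {"m10": [], "s10": [], "adj25": []}}
        for label in (0, 1):
            for seed in range(6):
                spec = SyntheticSlideSpec(
                    seed=100 * (label + 1) + seed, extent=(2392, 2392),
                    label=label, signal_scale="macro", effect=1.0,
                )
                slide, _ = render_slide(spec)
                arr = slide.level_array(0).astype(float)
                centers = slide.texture_truth["blob_centers"]
                # type each gland from its rendered pixels (purple: red low)
                est_h = []
                for cx, cy in centers:
                    x, y = int(cx), int(cy)
                    patch = arr[max(y - 10, 0): y + 11, max(x - 10, 0): x + 11, 0]
                    est_h.append(patch.mean() < 200)
                est_h = np.asarray(est_h)
                for cell in plan_grid(slide, cfg):
                    sets = enumerate_tile_sets(slide, cell, cfg, "p")
                    for ts in sets:
                        t10 = ts.images[10.0].astype(float)
                        stats[label]["m10"].append(t10.mean())
                        stats[label]["s10"].append(t10.std())
                    # 2.5x-window statistic: same-type fraction of nearby
                    # gland pairs inside the window's level-0 footprint
                    (x0, y0), side = cell.origin_xy_level0, cell.side_level0
                    inside = (
                        (centers[:, 0] >= x0) & (centers[:, 0] < x0 + side)
                        & (centers[:, 1] >= y0) & (centers[:, 1] < y0 + side)
                    )
                    c_in = centers[inside]
                    t_in = est_h[inside]
                    same = []
                    for i in range(len(c_in)):
                        for j in range(i + 1, len(c_in)):
                            if np.linalg.norm(c_in[i] - c_in[j]) < 600:
                                same.append(t_in[i] == t_in[j])
                    if same:
                        stats[label]["adj25"].append(np.mean(same))
        return stats

    def test_10x_summary_statistics_class_indistinguishable(self, tile_stats):
        for key in ("m10", "s10"):
            p = sp_stats.mannwhitneyu(tile_stats[0][key], tile_stats[1][key]).pvalue
            assert p > 0.01

    def test_2p5x_statistics_separate_classes(self, tile_stats):
        # domain segregation: nearby glands in one 2.5x field share a type
        # far more often in class 1
        p = sp_stats.mannwhitneyu(
            tile_stats[0]["adj25"], tile_stats[1]["adj25"], alternative="less"
        ).pvalue
        assert p < 0.01
        assert np.mean(tile_stats[1]["adj25"]) > np.mean(tile_stats[0]["adj25"])

    def test_effect_zero_classes_identically_distributed(self):
        # same seed, different label, effect 0 -> byte-identical rendering
        a, _ = render_slide(SyntheticSlideSpec(seed=9, extent=(640, 640),
                                               label=0, effect=0.0))
        b, _ = render_slide(SyntheticSlideSpec(seed=9, extent=(640, 640),
                                               label=1, effect=0.0))
        np.testing.assert_array_equal(a.level_array(0), b.level_array(0))

    def test_micro_signal_changes_dot_density(self):
        a, _ = render_slide(SyntheticSlideSpec(seed=9, extent=(1196, 1196),
                                               label=0, signal_scale="micro",
                                               effect=1.5))
        b, _ = render_slide(SyntheticSlideSpec(seed=9, extent=(1196, 1196),
                                               label=1, signal_scale="micro",
                                               effect=1.5))
        # denser hematoxylin dots -> darker tissue on average
        assert b.level_array(0).mean() < a.level_array(0).mean()
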