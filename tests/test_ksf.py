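"""Kinetic spatial filtering: templates, classification, suppression."""

import numpy as np
import pytest

from fltpet.core import DynamicPETSeries, FrameSchedule, ROIMask
from fltpet.errors import DegenerateROIError, InvalidConfigError, MaskConflictError
from fltpet.ksf import (
    KSFConfig,
    NearestTemplateClassifier,
    apply_ksf,
    build_templates,
    classify_voxels,
    ksf_metrics,
)


def toy_series(tacs_by_label, shape=(4, 4, 1)):
    """Series whose voxels follow per-label TACs; returns series + masks."""
    labels = list(tacs_by_label)
    n_frames = len(next(iter(tacs_by_label.values())))
    values = np.zeros(shape + (n_frames,))
    masks = {}
    per = np.array_split(np.arange(np.prod(shape)), len(labels))
    for lab, idx in zip(labels, per):
        m = np.zeros(np.prod(shape), dtype=bool)
        m[idx] = True
        m = m.reshape(shape)
        values[m, :] = tacs_by_label[lab]
        masks[lab] = ROIMask(m, label=lab)
    sched = FrameSchedule.from_durations(np.ones(n_frames))
    return DynamicPETSeries(values, (2.0, 2.0, 2.0), sched), masks


LIVER_TAC = np.array([8.0, 6.0, 4.0, 3.0, 2.5, 2.0])   # washout shape
TUMOR_TAC = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])   # accumulating shape


class TestBuildTemplates:
    def test_single_voxel_template_is_normalized_copy(self):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC},
                                   shape=(2, 1, 1))
        tmpl = build_templates(series, [masks["liver"]] + [masks["tumor"]])
        area = np.trapezoid(tmpl[0].values, tmpl[0].times)
        assert area == pytest.approx(1.0)
        assert np.allclose(tmpl[0].values / tmpl[0].values[0],
                           LIVER_TAC / LIVER_TAC[0])

    def test_identical_tacs_give_identical_templates(self):
        series, masks = toy_series({"a": LIVER_TAC, "b": LIVER_TAC}, shape=(6, 1, 1))
        ta, tb = build_templates(series, [masks["a"], masks["b"]])
        assert np.allclose(ta.values, tb.values)

    def test_overlapping_masks_rejected(self):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        overlap = ROIMask(np.ones(series.spatial_shape, dtype=bool), "all")
        with pytest.raises(MaskConflictError):
            build_templates(series, [masks["liver"], overlap])

    def test_phantom_templates_match_truth_curves(self, default_phantom, noise_free_phantom):
        from fltpet.core import extract_tac

        series, truth = default_phantom
        clean, _ = noise_free_phantom
        tmpl = build_templates(series, [truth.masks["liver"], truth.masks["lesion_1"]])
        for t, label in zip(tmpl, ["liver", "lesion_1"]):
            ref = extract_tac(clean, truth.masks[label]).values
            ref = ref / np.trapezoid(ref, t.times)
            assert np.allclose(t.values, ref, atol=0.02 * ref.max())


class TestClassifyVoxels:
    def test_exact_template_match(self):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        tmpl = build_templates(series, list(masks.values()))
        cmap = classify_voxels(series, tmpl)
        assert np.all(cmap[masks["liver"].mask] == "liver")
        assert np.all(cmap[masks["tumor"].mask] == "tumor")

    def test_scale_invariance(self):
        """A voxel at 5x the liver template amplitude is still liver."""
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        tmpl = build_templates(series, list(masks.values()))
        scaled = DynamicPETSeries(series.values * 5.0, series.voxel_size_mm,
                                  series.schedule)
        cmap = classify_voxels(scaled, tmpl)
        assert np.all(cmap[masks["liver"].mask] == "liver")

    @pytest.mark.parametrize("distance", ["normalized-l2", "one-minus-correlation"])
    @pytest.mark.parametrize("normalization", ["unit-area", "unit-peak"])
    def test_scale_invariance_all_configs(self, distance, normalization, rng):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        cfg = KSFConfig(distance=distance, normalization=normalization)
        tmpl = build_templates(series, list(masks.values()), cfg)
        gains = rng.uniform(0.2, 8.0, series.spatial_shape)
        scaled = DynamicPETSeries(series.values * gains[..., None],
                                  series.voxel_size_mm, series.schedule)
        assert np.array_equal(classify_voxels(scaled, tmpl, cfg),
                              classify_voxels(series, tmpl, cfg))

    def test_all_zero_voxel_is_other(self):
        from fltpet.ksf import TissueClassTemplate

        series, masks = toy_series({"liver": LIVER_TAC, "tumor": 0.0 * TUMOR_TAC})
        times = series.schedule.mid
        tmpl = [
            TissueClassTemplate("liver", times, LIVER_TAC / np.trapezoid(LIVER_TAC, times)),
            TissueClassTemplate("tumor", times, TUMOR_TAC / np.trapezoid(TUMOR_TAC, times)),
        ]
        cmap = classify_voxels(series, tmpl)
        assert np.all(cmap[masks["tumor"].mask] == "other")

    def test_noise_free_phantom_fully_accurate(self, noise_free_phantom):
        series, truth = noise_free_phantom
        tmpl = build_templates(series, [truth.masks["liver"], truth.masks["lesion_1"],
                                        truth.masks["blood"]])
        cmap = classify_voxels(series, tmpl)
        assert np.all(cmap[truth.masks["liver"].mask] == "liver")
        assert np.all(cmap[truth.masks["lesion_1"].mask] == "lesion_1")

    def test_sklearn_classifier_interface(self):
        times = np.arange(6, dtype=float) + 0.5
        X = np.vstack([LIVER_TAC, LIVER_TAC * 2, TUMOR_TAC, TUMOR_TAC * 0.5])
        y = np.array(["liver", "liver", "tumor", "tumor"])
        clf = NearestTemplateClassifier(times=times).fit(X, y)
        assert list(clf.classes_) == ["liver", "tumor"]
        assert list(clf.predict(np.vstack([TUMOR_TAC * 3, LIVER_TAC * 0.1]))) == \
            ["tumor", "liver"]


class TestApplyKSF:
    def window(self, series):
        return (0.0, series.schedule.total_minutes)

    def test_empty_exclusion_is_noop(self):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        cfg = KSFConfig(exclusion_classes=())
        tmpl = build_templates(series, list(masks.values()), cfg)
        res = apply_ksf(series, classify_voxels(series, tmpl, cfg), cfg,
                        self.window(series))
        assert np.allclose(res.filtered_summed, res.unfiltered_summed)

    def test_all_liver_fully_suppressed(self):
        series, masks = toy_series({"liver": LIVER_TAC, "tumor": TUMOR_TAC})
        cmap = np.full(series.spatial_shape, "liver", dtype="U32")
        res = apply_ksf(series, cmap, KSFConfig(), self.window(series))
        assert np.all(res.filtered_summed == 0.0)

    def test_majority_filter_relabels_isolated_voxel(self):
        """A lone tumor-labeled voxel deep inside liver is relabeled."""
        shape = (5, 5, 5)
        cmap = np.full(shape, "liver", dtype="U32")
        cmap[2, 2, 2] = "tumor"
        series = DynamicPETSeries(np.ones(shape + (6,)), (2, 2, 2),
                                  FrameSchedule.from_durations(np.ones(6)))
        res = apply_ksf(series, cmap, KSFConfig(spatial_filter_radius=1),
                        self.window(series))
        assert np.all(res.class_map == "liver")

    def test_suppression_monotone_in_exclusion_set(self, default_phantom):
        """Enlarging the exclusion set never increases any voxel."""
        series, truth = default_phantom
        tmpl = build_templates(series, [truth.masks["liver"], truth.masks["lesion_1"],
                                        truth.masks["blood"]])
        cmap = classify_voxels(series, tmpl)
        prev = None
        for excl in [(), ("liver",), ("liver", "blood"),
                     ("liver", "blood", "lesion_1")]:
            res = apply_ksf(series, cmap, KSFConfig(exclusion_classes=excl),
                            (50.0, 59.0))
            assert np.all(res.filtered_summed <= res.unfiltered_summed + 1e-12)
            if prev is not None:
                assert np.all(res.filtered_summed <= prev + 1e-12)
            prev = res.filtered_summed


class TestKSFMetrics:
    def test_no_filtering_no_reduction(self):
        vol = np.random.default_rng(0).uniform(1, 5, (3, 3, 3))
        m = ROIMask(np.ones((3, 3, 3), dtype=bool))
        out = ksf_metrics(vol, vol, m, m)
        assert out["tumor_pct_reduction"] == pytest.approx(0.0)

    def test_fully_suppressed_liver(self):
        vol = np.full((3, 3, 3), 4.0)
        m = ROIMask(np.ones((3, 3, 3), dtype=bool))
        out = ksf_metrics(vol, np.zeros_like(vol), m, m)
        assert out["liver_pct_reduction"] == pytest.approx(100.0)
        assert np.isinf(out["post_filter_tumor_to_liver"])
        assert out["liver_fully_suppressed"]

    def test_zero_unfiltered_mean_rejected(self):
        m = ROIMask(np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(DegenerateROIError):
            ksf_metrics(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), m, m)

    def test_phantom_liver_suppressed_more_than_tumor(self, default_phantom):
        """Liver-like voxels vanish while the tumor core survives, so the
        tumor-to-liver ratio improves."""
        series, truth = default_phantom
        tmpl = build_templates(series, [truth.masks["liver"], truth.masks["lesion_1"],
                                        truth.masks["blood"]])
        cfg = KSFConfig()
        res = apply_ksf(series, classify_voxels(series, tmpl, cfg), cfg, (50.0, 59.0))
        out = ksf_metrics(res.unfiltered_summed, res.filtered_summed,
                          truth.masks["lesion_1"], truth.masks["liver"])
        assert out["liver_pct_reduction"] > out["tumor_pct_reduction"]
        pre_ratio = (res.unfiltered_summed[truth.masks["lesion_1"].mask].max()
                     / res.unfiltered_summed[truth.masks["liver"].mask].mean())
        assert out["post_filter_tumor_to_liver"] > pre_ratio
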