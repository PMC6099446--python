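"""Threshold translation, voxel classification, reports, paired statistics."""

import numpy as np
import pandas as pd
import pytest

from lungaerate.imaging import Mask, RoiSpec, Volume
from lungaerate.invivo import (LABEL_NONAERATED, LABEL_NORMAL, LABEL_POOR,
                               ThresholdSet, atelectasis_reference,
                               classify_voxels, compartment_report,
                               paired_wilcoxon, quantify_scan,
                               rm_anova_roi_time, sidak_adjust,
                               threshold_sensitivity, translate_thresholds,
                               ventro_dorsal_split)


def _normalized(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(data=np.asarray(data, dtype=float), spacing=spacing,
                  units="muscle-normalized")


class TestTranslateThresholds:
    def test_study_values(self):
        thr = translate_thresholds(0.92, 0.70, 0.28)
        assert thr.t_nonaerated == pytest.approx(0.644)
        assert thr.t_poor == pytest.approx(0.2576)
        assert thr.provenance["rounded_values"] == (0.64, 0.26)

    def test_identity_at_unit_reference(self):
        thr = translate_thresholds(1.0, 0.70, 0.28)
        assert (thr.t_nonaerated, thr.t_poor) == (0.70, 0.28)

    def test_rounded_flag_applies_two_decimals(self):
        thr = translate_thresholds(0.92, 0.70, 0.28, rounded=True)
        assert (thr.t_nonaerated, thr.t_poor) == (0.64, 0.26)
        assert abs(thr.t_nonaerated
                   - thr.provenance["full_precision"][0]) < 0.01

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            translate_thresholds(0.0, 0.70, 0.28)


class TestAtelectasisReference:
    def test_painted_value_recovered(self):
        vol = _normalized(np.full((30, 30, 30), 0.10))
        vol.data[8:22, 8:22, 8:22] = 0.92
        lung = Mask.from_volume(vol, vol.data > 0.5)
        roi = RoiSpec("cube", (14.5, 14.5, 14.5), size_cm3=2.03)
        assert atelectasis_reference(vol, roi, lung) == pytest.approx(0.92)

    def test_roi_leaking_outside_mask_rejected(self):
        vol = _normalized(np.full((30, 30, 30), 0.92))
        lung = np.zeros((30, 30, 30), dtype=bool)
        lung[12:17, 12:17, 12:17] = True   # smaller than the 12.66 mm cube
        with pytest.raises(ValueError, match="outside the lung mask"):
            atelectasis_reference(vol, RoiSpec("cube", (14.5, 14.5, 14.5),
                                               size_cm3=2.03),
                                  Mask.from_volume(vol, lung))

    def test_requires_normalized_volume(self):
        vol = Volume(data=np.full((20, 20, 20), 100.0), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="muscle-normalized"):
            atelectasis_reference(vol, RoiSpec("cube", (10, 10, 10),
                                               size_cm3=2.03))


class TestClassification:
    def test_rule_on_three_voxels(self):
        vol = _normalized(np.array([0.70, 0.40, 0.10]).reshape(3, 1, 1))
        mask = Mask.from_volume(vol, np.ones((3, 1, 1), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        labels = classify_voxels(vol, mask, thr)
        assert list(labels[:, 0, 0]) == [LABEL_NONAERATED, LABEL_POOR,
                                         LABEL_NORMAL]

    def test_all_above_threshold_is_fully_nonaerated(self):
        vol = _normalized(np.full((5, 5, 5), 0.9))
        mask = Mask.from_volume(vol, np.ones((5, 5, 5), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        rep = compartment_report(classify_voxels(vol, mask, thr), mask, thr)
        assert rep.percent_of_tlv["non_aerated"] == pytest.approx(100.0)

    def test_attenuation_scale_rejected_on_intensity_volume(self):
        vol = _normalized(np.full((5, 5, 5), 0.9))
        mask = Mask.from_volume(vol, np.ones((5, 5, 5), dtype=bool))
        thr = ThresholdSet("attenuation", 0.70, 0.28)
        with pytest.raises(ValueError, match="attenuation-scale"):
            classify_voxels(vol, mask, thr)

    def test_scale_consistency_of_labels(self):
        rng = np.random.default_rng(8)
        vol = _normalized(rng.uniform(0, 1, (8, 8, 8)))
        mask = Mask.from_volume(vol, np.ones((8, 8, 8), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        l1 = classify_voxels(vol, mask, thr)
        scaled = _normalized(vol.data * 3.7)
        thr2 = ThresholdSet("muscle-normalized-intensity", 0.64 * 3.7,
                            0.26 * 3.7)
        l2 = classify_voxels(scaled, mask, thr2)
        assert np.array_equal(l1, l2)


class TestCompartmentReport:
    def test_counts_to_volumes(self):
        data = np.full((10, 10, 10), 0.1)
        data.flat[:100] = 0.9
        vol = _normalized(data)
        mask = Mask.from_volume(vol, np.ones((10, 10, 10), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        rep = quantify_scan(vol, mask, thr)
        assert rep.volumes_ml["non_aerated"] == pytest.approx(0.1)
        assert rep.percent_of_tlv["non_aerated"] == pytest.approx(10.0)
        assert sum(rep.percent_of_tlv.values()) == pytest.approx(100.0)
        assert sum(rep.volumes_ml.values()) == pytest.approx(
            rep.total_lung_volume_ml, rel=1e-9)


class TestVentroDorsalSplit:
    @staticmethod
    def _mask(shape=(10, 12, 8), labels=("LR", "PA", "IS")):
        m = np.zeros(shape, dtype=bool)
        m[2:8, 2:10, 2:6] = True
        return Mask(data=m, spacing=(1, 1, 1), axis_labels=labels)

    def test_partition_properties(self):
        mask = self._mask()
        ventral, dorsal = ventro_dorsal_split(mask)
        assert not (ventral.data & dorsal.data).any()
        assert np.array_equal(ventral.data | dorsal.data, mask.data)
        # symmetric mask: halves within one slice plane of each other
        diff = abs(int(ventral.data.sum()) - int(dorsal.data.sum()))
        assert diff <= mask.data.any(axis=1).sum()

    def test_orientation_respected(self):
        mask = self._mask()          # "PA": posterior at low indices
        ventral, dorsal = ventro_dorsal_split(mask)
        assert dorsal.data[:, :6, :].sum() == dorsal.data.sum()
        flipped = self._mask(labels=("LR", "AP", "IS"))
        v2, d2 = ventro_dorsal_split(flipped)
        assert np.array_equal(v2.data, dorsal.data)

    def test_gradient_volume_has_higher_dorsal_mean(self):
        mask = self._mask()
        grad = np.tile(np.linspace(0.3, 0.1, 12)[None, :, None], (10, 1, 8))
        vol = _normalized(grad)      # posterior (low index) brighter
        ventral, dorsal = ventro_dorsal_split(mask)
        from lungaerate.imaging import mean_signal
        assert mean_signal(vol, dorsal) > mean_signal(vol, ventral)

    def test_missing_axis_label_rejected(self):
        mask = self._mask(labels=("LR", "XX", "IS"))
        with pytest.raises(ValueError, match="anterior-posterior"):
            ventro_dorsal_split(mask)


class TestThresholdSensitivity:
    def test_no_histogram_mass_near_thresholds_gives_zero_deltas(self):
        data = np.where(np.arange(1000).reshape(10, 10, 10) < 100, 0.9, 0.1)
        vol = _normalized(data.astype(float))
        mask = Mask.from_volume(vol, np.ones((10, 10, 10), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        rows = threshold_sensitivity(vol, mask, thr)
        assert all(r["max_abs_delta_percent_tlv"] == 0.0 for r in rows)

    def test_raising_nonaerated_threshold_never_grows_that_class(self):
        rng = np.random.default_rng(4)
        vol = _normalized(rng.uniform(0, 1, (12, 12, 12)))
        mask = Mask.from_volume(vol, np.ones((12, 12, 12), dtype=bool))
        thr = ThresholdSet("muscle-normalized-intensity", 0.64, 0.26)
        base = quantify_scan(vol, mask, thr)
        up = quantify_scan(vol, mask, thr.scaled(factor_non=1.05))
        assert up.percent_of_tlv["non_aerated"] <= \
            base.percent_of_tlv["non_aerated"]


class TestPairedWilcoxon:
    def test_six_uniform_differences(self):
        p = paired_wilcoxon([0] * 6, [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(0.0277, abs=5e-4)
        assert round(p, 3) == 0.028

    def test_single_nonzero_pair_is_insignificant(self):
        p = paired_wilcoxon([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 8])
        assert p > 0.3

    def test_sign_symmetry(self):
        pre = [1.0, 2.0, 3.5, 4.0, 6.0]
        post = [2.0, 1.5, 5.0, 4.5, 7.0]
        assert paired_wilcoxon(pre, post) == pytest.approx(
            paired_wilcoxon(post, pre))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2, 3], [2, 3, 4])


class TestRmAnova:
    def test_sidak_worked_example(self):
        assert sidak_adjust(0.05, 2) == pytest.approx(0.0975)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n = 6
        vpre = rng.normal(0.10, 0.02, n)
        dpre = vpre + rng.normal(0.06, 0.02, n)
        vpost = rng.normal(0.12, 0.02, n)
        dpost = vpost + rng.normal(0.08, 0.02, n)
        mine = rm_anova_roi_time(vpre, dpre, vpost, dpost)
        rows = []
        for i in range(n):
            for roi, t, v in (("v", "pre", vpre[i]), ("d", "pre", dpre[i]),
                              ("v", "post", vpost[i]), ("d", "post", dpost[i])):
                rows.append({"subj": i, "roi": roi, "time": t, "y": v})
        aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y",
                          within=["roi", "time"], subject="subj")
        ref = dict(zip(aov["Source"], aov["p_unc"]))
        assert mine["p_roi"] == pytest.approx(ref["roi"], rel=1e-6)
        assert mine["p_time"] == pytest.approx(ref["time"], rel=1e-6)
        assert mine["p_interaction"] == pytest.approx(ref["roi * time"],
                                                      rel=1e-6)

    def test_dorsal_offset_power_without_time_effect(self):
        # ROI effect 3x the noise SD, no time effect: the ROI factor should
        # be detected in nearly every replicate, the time factor rarely
        roi_hits = time_hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            base = rng.normal(0.10, 0.01, 6)
            noise = lambda: rng.normal(0.0, 0.01, 6)
            vpre, vpost = base + noise(), base + noise()
            dpre, dpost = base + 0.03 + noise(), base + 0.03 + noise()
            res = rm_anova_roi_time(vpre, dpre, vpost, dpost)
            roi_hits += res["p_roi"] < 0.05
            time_hits += res["p_time"] < 0.05
        assert roi_hits >= 0.9 * n_runs
        assert time_hits <= 0.2 * n_runs

    def test_identical_values_guarded(self):
        res = rm_anova_roi_time([1, 1, 1], [1, 1, 1], [1, 1, 1], [1, 1, 1])
        assert res["p_roi"] == 1.0
        assert res["p_time"] == 1.0

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_roi_time([1, 2], [1, 2, 3], [1, 2, 3], [1, 2, 3])
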