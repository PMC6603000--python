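"""Vesicle pooling, decision tree, summaries and well normalisation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oracles import classify_oracle, random_feature_tuples
from rosellapipe.classify import (
    VesicleRecord,
    classify_features,
    compute_noncircular_mask,
    normalize_wells,
    pool_vesicles,
    summarize_field,
)
from rosellapipe.filters import VOXEL_VOLUME_UM3, label_volume


def _record(cls: str) -> VesicleRecord:
    return VesicleRecord(
        label=0, vesicle_class=cls, volume_voxels=100,
        volume_um3=100 * VOXEL_VOLUME_UM3, centroid=(0, 0, 0),
        mean_red_raw=500.0, mean_green_raw=500.0, q3_green=0.0, q3_red=0.0,
        median_ratio=1.0, overlap_phluorin=0.0, overlap_dsred=0.0,
        overlap_autolyso=0.0, overlap_autophagosome=0.0, overlap_noncircular=0.0,
        center_green=0.0, surface_green=0.0, eccentricity=0.0,
        touches_border=False, major_axis_um=1.0,
    )


class TestDecisionTree:
    def test_matches_independent_oracle_on_random_tuples(self, rng):
        for feats in random_feature_tuples(rng, 2000):
            assert classify_features(feats) == classify_oracle(feats)

    @pytest.mark.parametrize(
        ("updates", "expected"),
        [
            ({"overlap_autophagosome": 0.4}, "autophagosome"),
            (
                {"overlap_autophagosome": 0.4, "overlap_noncircular": 0.2,
                 "overlap_dsred": 0.3, "overlap_phluorin": 0.05},
                "late_autolysosome",
            ),
            (
                {"overlap_phluorin": 0.30, "overlap_dsred": 0.40,
                 "median_ratio": 2.4},
                "phagophore",
            ),
            ({"q3_green": 7600.0, "q3_red": 4100.0}, "phagophore"),
            ({"center_green": 1300.0, "surface_green": 1000.0}, "phagophore"),
            (
                {"overlap_dsred": 0.30, "overlap_phluorin": 0.05,
                 "median_ratio": 1.1},
                "late_autolysosome",
            ),
            (
                {"overlap_dsred": 0.30, "overlap_phluorin": 0.20,
                 "median_ratio": 2.2},
                "early_autolysosome",
            ),
            ({"overlap_autolyso": 0.5, "median_ratio": 2.5}, "early_autolysosome"),
            ({}, "unclassified"),
        ],
    )
    def test_stage_signature_examples(self, updates, expected):
        base = {
            "overlap_autophagosome": 0.0, "overlap_noncircular": 0.0,
            "overlap_phluorin": 0.0, "overlap_dsred": 0.0,
            "overlap_autolyso": 0.0, "median_ratio": 3.0,
            "q3_green": 0.0, "q3_red": 0.0,
            # neutral profile: centre equals surface, so neither the
            # centre-bright nor the centre-dim rule can fire
            "center_green": 1000.0, "surface_green": 1000.0,
        }
        base.update(updates)
        assert classify_features(base) == expected


class TestPoolVesicles:
    shape = (3, 48, 48)

    def _mask(self, *boxes):
        m = np.zeros(self.shape, dtype=bool)
        for z, y, x in boxes:
            m[z, y, x] = True
        return m

    def test_dim_red_vesicle_excluded(self):
        mask = self._mask((slice(0, 3), slice(10, 16), slice(10, 16)))
        red = np.full(self.shape, 250.0)
        labels = pool_vesicles(mask, np.zeros_like(mask), red)
        assert labels.max() == 0

    def test_border_touching_vesicle_excluded(self):
        mask = self._mask((slice(0, 3), slice(0, 6), slice(10, 16)))
        red = np.full(self.shape, 500.0)
        labels = pool_vesicles(mask, np.zeros_like(mask), red)
        assert labels.max() == 0

    def test_perimeter_carving_keeps_vesicles_split(self):
        # two blobs joined only through an autophagosome-mask ring between them
        mask = np.zeros(self.shape, dtype=bool)
        mask[:, 20:28, 8:20] = True
        mask[:, 20:28, 20:32] = True
        ap = np.zeros_like(mask)
        ap[:, 18:30, 18:22] = True  # its 2D perimeter cuts the junction
        red = np.full(self.shape, 500.0)
        labels = pool_vesicles(mask | ap, ap, red)
        # left blob, right blob, and the ring interior itself stay separate
        assert labels.max() == 3
        assert labels[1, 24, 10] != labels[1, 24, 30]

    def test_interior_vesicle_retained_and_relabelled(self):
        mask = self._mask((slice(0, 3), slice(10, 16), slice(10, 16)),
                          (slice(0, 3), slice(30, 36), slice(30, 36)))
        red = np.full(self.shape, 250.0)
        red[:, 30:36, 30:36] = 800.0
        labels = pool_vesicles(mask, np.zeros_like(mask), red)
        assert labels.max() == 1
        assert (labels[:, 30:36, 30:36] == 1).all()


class TestNoncircularMask:
    def _labels_from(self, mask2d):
        vol = np.zeros((1,) + mask2d.shape, dtype=bool)
        vol[0] = mask2d
        labels, _ = label_volume(vol)
        return labels

    def test_bar_flagged_circle_and_mild_ellipse_not(self):
        yy, xx = np.mgrid[0:64, 0:64]
        bar = np.zeros((64, 64), dtype=bool)
        bar[30:32, 10:30] = True  # 20 x 2: eccentricity ~ 0.995
        circle = (yy - 20) ** 2 + (xx - 45) ** 2 <= 64
        ellipse = ((yy - 50) / 10.0) ** 2 + ((xx - 40) / 9.0) ** 2 <= 1  # e ~ 0.44
        assert compute_noncircular_mask(self._labels_from(bar)).any()
        assert not compute_noncircular_mask(self._labels_from(circle)).any()
        assert not compute_noncircular_mask(self._labels_from(ellipse)).any()


class TestSummarize:
    def test_rate_constant_on_constructed_counts(self):
        records = (
            [_record("phagophore")] * 41
            + [_record("autophagosome")] * 10
            + [_record("early_autolysosome")] * 10
            + [_record("late_autolysosome")] * 80
        )
        s = summarize_field(records)
        assert s.autophagic_vacuoles == 100
        assert s.autophagy_rate == pytest.approx(0.41)
        assert s.rate_defined

    def test_empty_field_rate_flagged(self):
        s = summarize_field([])
        assert s.n_vesicles_total == 0
        assert s.autophagy_rate == 0.0
        assert not s.rate_defined

    def test_zero_phagophores(self):
        records = [_record("late_autolysosome")] * 50
        s = summarize_field(records)
        assert s.autophagy_rate == 0.0
        assert s.rate_defined

    def test_volume_arithmetic_exact(self):
        assert 1000 * VOXEL_VOLUME_UM3 == pytest.approx(18.524416, abs=1e-9)
        assert 150 * VOXEL_VOLUME_UM3 == pytest.approx(2.7786624, abs=1e-9)


class TestNormalizeWells:
    def test_uniform_wells_all_one(self):
        counts = pd.DataFrame({"phagophore": [5, 5, 5]}, index=["a", "b", "c"])
        out = normalize_wells(counts)
        assert (out["phagophore"] == 1.0).all()

    def test_outlier_clipped_to_two(self):
        counts = pd.DataFrame({"c": [1.0, 1.0, 1.0, 9.0]})
        out = normalize_wells(counts)
        assert out["c"].iloc[-1] == 2.0

    def test_zero_mean_category_warned_and_dropped(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.warns(UserWarning):
            out = normalize_wells(counts)
        assert list(out.columns) == ["a"]

    def test_rescale_mode_spans_clip_range(self):
        counts = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = normalize_wells(counts, mode="rescale")
        assert out["a"].min() == 0.0
        assert out["a"].max() == 2.0


class TestMonotonicity:
    def test_adding_red_vesicle_adds_one_autolysosome(self):
        """Noise-free fields differing by one rendered late autolysosome."""
        from rosellapipe import run_autophagy_field
        from rosellapipe.simulate import SceneSpec, render_scene

        common = dict(
            shape=(5, 128, 128), seed=7, n_phagophore=2, n_late_autolysosome=3,
            poisson_noise=False, read_noise_sd=0.0,
        )
        base, _ = render_scene(SceneSpec(**common))
        more, _ = render_scene(SceneSpec(**{**common, "n_late_autolysosome": 4}))
        s_base = run_autophagy_field(base).summary
        s_more = run_autophagy_field(more).summary
        extra_late = s_more.n_late_autolysosome - s_base.n_late_autolysosome
        extra_early = s_more.n_early_autolysosome - s_base.n_early_autolysosome
        assert extra_late + extra_early == 1
        assert s_more.n_phagophore == s_base.n_phagophore
        assert s_more.n_autophagosome == s_base.n_autophagosome
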