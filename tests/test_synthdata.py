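"""Phantom generators: atlas structure, lesion growth accuracy, cohort
labeling, and seed purity."""

import numpy as np
import pytest
from scipy import ndimage

from ads.models import FEATURE_GAMMA_ILVR, FEATURE_GAMMA_OLVR
from ads.qfv import extract_qfv
from ads.synthdata import (
    PhantomSpec,
    make_adc_phantom,
    make_cohort,
    make_lesion,
    make_phantom_atlas,
)


class TestPhantomAtlas:
    def test_bilateral_rois_are_mirror_balanced(self, atlas):
        half = (atlas.structural.grid.shape[0] - 1) / 2.0
        for vol, unpaired in ((atlas.arterial, ()), (atlas.structural, ("brainstem",))):
            x = np.arange(vol.grid.shape[0])[:, None, None]
            for row in vol.table:
                if row.name in unpaired:
                    continue
                roi = vol.labels == row.id
                left = int((roi & (x < half)).sum())
                right = int((roi & (x > half)).sum())
                assert abs(left - right) / max(left, right) <= 0.05

    def test_rois_partition_the_brain(self, atlas):
        brain = atlas.brain.as_bool()
        for vol in (atlas.arterial, atlas.structural):
            assert ((vol.labels > 0) == brain).all()

    def test_ventricles_have_five_subregions(self, atlas):
        assert sorted(atlas.ventricles.voxel_counts()) == [1, 2, 3, 4, 5]
        assert all(c > 0 for c in atlas.ventricles.voxel_counts().values())

    def test_seed_purity(self, spec):
        a = make_phantom_atlas(spec)
        b = make_phantom_atlas(spec)
        np.testing.assert_array_equal(a.structural.labels, b.structural.labels)
        np.testing.assert_array_equal(a.arterial.labels, b.arterial.labels)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(16, 16, 16))
        with pytest.raises(ValueError):
            PhantomSpec(n_arterial_pairs=1)


class TestMakeLesion:
    def test_targets_hit_within_tolerance(self, small_atlas):
        targets = {"structure_1": 0.61}
        mask = make_lesion(small_atlas.structural, targets, tol=0.02, seed=3)
        q = extract_qfv(mask, small_atlas.structural)
        assert 0.59 <= q.fractions["structure_1"] <= 0.63

    def test_multi_target_with_bridging(self, atlas):
        targets = {"structure_1": 0.3, "structure_5": 0.25}
        mask = make_lesion(atlas.structural, targets, tol=0.02, seed=4)
        q = extract_qfv(mask, atlas.structural)
        for roi, frac in targets.items():
            assert abs(q.fractions[roi] - frac) <= 0.021
        # connectivity: one connected component
        n_comp = ndimage.label(mask.as_bool())[1]
        assert n_comp == 1

    def test_untargeted_rois_stay_small(self, small_atlas):
        mask = make_lesion(small_atlas.structural, {"structure_2": 0.4}, seed=5)
        q = extract_qfv(mask, small_atlas.structural)
        for roi, frac in q.fractions.items():
            if roi != "structure_2":
                assert frac <= 0.02 + 2 / q.roi_voxels[roi]

    def test_coalescence_into_neighbors(self, small_atlas):
        mask = make_lesion(small_atlas.structural, {"structure_1": 0.7}, seed=6)
        q = extract_qfv(mask, small_atlas.structural)
        others = [f for r, f in q.fractions.items() if r != "structure_1"]
        assert max(others) > 0  # spillover across the semantic boundary

    def test_empty_targets_rejected(self, small_atlas):
        with pytest.raises(ValueError, match="empty target"):
            make_lesion(small_atlas.structural, {}, seed=0)

    def test_unknown_roi_rejected(self, small_atlas):
        with pytest.raises(KeyError):
            make_lesion(small_atlas.structural, {"nope": 0.5}, seed=0)

    def test_seed_purity(self, small_atlas):
        a = make_lesion(small_atlas.structural, {"structure_1": 0.3}, seed=11)
        b = make_lesion(small_atlas.structural, {"structure_1": 0.3}, seed=11)
        np.testing.assert_array_equal(a.values, b.values)


class TestMakeCohort:
    def test_minimum_size_enforced(self, small_atlas):
        with pytest.raises(ValueError):
            make_cohort(small_atlas, 5, seed=0)

    def test_noise_free_labels_follow_the_overlap_rule(self, small_atlas, small_spec):
        cases = make_cohort(
            small_atlas, 20, noise=0.0, seed=17, with_hydro=False, spec=small_spec
        )
        tau = small_spec.label_rule_tau
        for c in cases:
            for key, y in c.labels.items():
                assert y == int(c.features[key] >= tau)

    def test_requested_prevalence_within_binomial_bounds(self, cohort, spec, atlas):
        from scipy.stats import binom

        n = len(cohort)
        n_rois = len(atlas.structural.roi_names)
        # draws are redrawn when empty, so the effective per-ROI rate is
        # conditioned on at least one ROI being drawn
        p_empty = (1 - spec.prevalence) ** n_rois
        p_eff = spec.prevalence / (1 - p_empty)
        lo, hi = binom.ppf([0.025, 0.975], n, p_eff)
        for roi in atlas.structural.roi_names:
            drawn = sum(1 for c in cohort if roi in c.meta["targets"])
            assert lo <= drawn <= hi, roi

    def test_neighbor_label_correlation_positive(self, cohort, atlas):
        # spatially adjacent structural ROIs co-occur in lesions
        vol = atlas.structural
        adj = []
        for i, a in enumerate(vol.roi_ids):
            grown = ndimage.binary_dilation(vol.labels == a)
            for b in vol.roi_ids[i + 1:]:
                if (grown & (vol.labels == b)).any():
                    adj.append((vol.name_of(a), vol.name_of(b)))
        assert adj
        y = {
            r: np.array([c.labels[f"structural:{r}"] for c in cohort])
            for r in vol.roi_names
        }
        corrs = [np.corrcoef(y[a], y[b])[0, 1] for a, b in adj]
        assert np.mean(corrs) > 0

    def test_severe_imbalance_supported(self, small_atlas, small_spec):
        prevalence = {r: 0.05 for r in small_atlas.structural.roi_names}
        prevalence["structure_1"] = 0.9  # keep draws mostly nonempty
        cases = make_cohort(
            small_atlas, 25, prevalence=prevalence, seed=23,
            with_hydro=False, spec=small_spec,
        )
        assert len(cases) == 25

    def test_seed_purity(self, small_atlas, small_spec):
        a = make_cohort(small_atlas, 20, seed=31, with_hydro=True, spec=small_spec)
        b = make_cohort(small_atlas, 20, seed=31, with_hydro=True, spec=small_spec)
        assert [c.features for c in a] == [c.features for c in b]
        assert [c.labels for c in a] == [c.labels for c in b]
        assert [c.hydrocephalus for c in a] == [c.hydrocephalus for c in b]

    def test_hydro_features_attached(self, cohort):
        for c in cohort[:10]:
            assert 0.0 <= c.features[FEATURE_GAMMA_OLVR] <= 1.0
            assert 0.0 <= c.features[FEATURE_GAMMA_ILVR] <= 1.0
            assert c.hydrocephalus in (0, 1)


class TestADCPhantom:
    def test_seed_purity(self, small_atlas):
        a = make_adc_phantom(small_atlas.ventricles, seed=2)
        b = make_adc_phantom(small_atlas.ventricles, seed=2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_positive_and_unit_scaled(self, small_atlas):
        adc = make_adc_phantom(small_atlas.ventricles, seed=3)
        assert (adc.values > 0).all()
        assert float(np.percentile(adc.values, 99)) < 1.0
        assert adc.units == "mm^2/s"

    def test_invalid_scale_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            make_adc_phantom(small_atlas.ventricles, ventricle_scale=0.0)
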