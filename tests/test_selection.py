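"""Tests of the region-selection stage: histogram mode estimation, the
hyperintensity threshold, WM-mask correction with geodesic dilation, and
the three anatomical filters at their exact strictness boundaries."""

import warnings

import numpy as np
import pytest

from whasa.core import BinaryMask, Volume
from whasa.phantom import PhantomConfig, generate_phantom
from whasa.selection import (SelectionParams, correct_wm_mask,
                             estimate_normal_mode,
                             filter_by_wm_overlap, lower_slices,
                             remove_brainstem_false_positives,
                             remove_cortical_false_positives, run_whasa,
                             select_hyperintense_regions, wmh_threshold)
from whasa.watershed import PiecewiseResult
from whasa.core import LabelMap

from conftest import make_mask, make_volume


class TestEstimateNormalMode:
    def test_two_mode_mixture_recovers_tissue_mean(self, rng):
        n = 40000
        vals = np.concatenate([rng.normal(5, 2, int(n * 0.6)),
                               rng.normal(100, 5, int(n * 0.4))])
        vol = make_volume(vals.reshape(40, 50, 20))
        i_tilde = estimate_normal_mode(vol, bins=256)
        bin_width = (vals.max() - vals.min()) / 256
        assert abs(i_tilde - 100) <= max(bin_width, 1.0)

    def test_third_lesion_bump_ignored(self, rng):
        vals = np.concatenate([rng.normal(5, 2, 29000),
                               rng.normal(100, 5, 20000),
                               rng.normal(160, 3, 1000)])
        vol = make_volume(vals.reshape(50, 50, 20))
        i_tilde = estimate_normal_mode(vol, bins=256)
        assert 90 < i_tilde < 110  # the 160 bump is the third maximum

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="unimodal"):
            estimate_normal_mode(make_volume(np.full((10, 10, 5), 3.0)))

    def test_mask_restricts_domain(self, rng):
        # inside the mask: modes at 10 and 50; outside: a large cluster at
        # 25 that would otherwise be the second histogram maximum
        data = np.zeros((30, 20, 10))
        data[:10] = rng.normal(10, 1.5, size=(10, 20, 10))
        data[10:20] = rng.normal(50, 1.5, size=(10, 20, 10))
        data[20:] = rng.normal(25, 1.5, size=(10, 20, 10))
        vol = make_volume(np.clip(data, 0, None))
        mask = np.zeros(data.shape, dtype=bool)
        mask[:20] = True
        with_mask = estimate_normal_mode(vol, mask=mask)
        without = estimate_normal_mode(vol)
        assert abs(with_mask - 50) < 3
        assert abs(without - 25) < 3


class TestThreshold:
    @pytest.mark.parametrize("i_tilde,lam,expected",
                             [(100, 15, 130), (0, 7, 14), (50, 0, 50)])
    def test_formula(self, i_tilde, lam, expected):
        assert wmh_threshold(i_tilde, lam) == expected


def piecewise_from_labels(labels_3d, means):
    pw_img = np.zeros(labels_3d.shape)
    for rid, m in means.items():
        pw_img[labels_3d == rid] = m
    return PiecewiseResult(
        labels=LabelMap(data=labels_3d.astype(np.int32)),
        region_means=means,
        piecewise_image=Volume(data=pw_img),
        n_blocks=[2] * labels_3d.shape[2],
        converged=[True] * labels_3d.shape[2],
    )


class TestSelectHyperintense:
    def test_strictly_above_threshold(self):
        labels = np.zeros((4, 6, 1), dtype=int)
        labels[:, :2, 0] = 1
        labels[:, 2:4, 0] = 2
        labels[:, 4:, 0] = 3
        t = 130.0
        pw = piecewise_from_labels(labels, {1: 130.0, 2: 130.0 + 1e-9, 3: 100.0})
        out = select_hyperintense_regions(pw, t)
        assert not out.data[labels == 1].any()   # mean == T excluded
        assert out.data[labels == 2].all()       # mean just above included
        assert not out.data[labels == 3].any()

    def test_no_region_above_gives_empty(self):
        labels = np.ones((3, 3, 1), dtype=int)
        pw = piecewise_from_labels(labels, {1: 90.0})
        assert select_hyperintense_regions(pw, 130.0).count() == 0


class TestCorrectWMMask:
    def grids(self, shape):
        gm = np.zeros(shape)
        wm = np.zeros(shape)
        csf = np.zeros(shape)
        flair = np.zeros(shape)
        return gm, wm, csf, flair

    def test_bright_gm_voxel_adjacent_to_wm_added(self):
        shape = (7, 7, 1)
        gm, wm, csf, flair = self.grids(shape)
        wm[0:3, :, 0] = 1.0
        gm[3:6, :, 0] = 1.0
        nvox = int((gm > 0.5).sum())
        flair[gm > 0.5] = np.linspace(90, 110, nvox)  # varied GM intensities
        flair[3, 3, 0] = 200.0  # clearly in the top 5% of GM intensities
        out = correct_wm_mask(make_volume(gm), make_volume(wm),
                              make_volume(csf), make_volume(flair))
        assert out.data[3, 3, 0]
        assert out.data[wm > 0.5].all()

    def test_bright_csf_voxel_adjacent_to_wm_added(self):
        shape = (7, 7, 1)
        gm, wm, csf, flair = self.grids(shape)
        wm[0:3, :, 0] = 1.0
        gm[5:7, :, 0] = 1.0
        csf[3:5, :, 0] = 1.0
        nvox = int((gm > 0.5).sum())
        flair[gm > 0.5] = np.linspace(90, 110, nvox)
        flair[3, 2, 0] = 150.0  # brighter than mean GM, touches WM row 2
        out = correct_wm_mask(make_volume(gm), make_volume(wm),
                              make_volume(csf), make_volume(flair))
        assert out.data[3, 2, 0]

    def test_isolated_outlier_not_reachable_not_added(self):
        # geodesic-dilation oracle on a 7x7 fixture: an outlier with no
        # 4-connected path to WM through outliers stays out
        shape = (7, 7, 1)
        gm, wm, csf, flair = self.grids(shape)
        wm[0:2, :, 0] = 1.0
        gm[2:7, :, 0] = 1.0
        nvox = int((gm > 0.5).sum())
        flair[gm > 0.5] = np.linspace(90, 110, nvox)
        flair[5, 3, 0] = 200.0  # bright but 3 rows away from WM
        out = correct_wm_mask(make_volume(gm), make_volume(wm),
                              make_volume(csf), make_volume(flair))
        assert not out.data[5, 3, 0]

    def test_chain_of_outliers_is_followed(self):
        shape = (7, 7, 1)
        gm, wm, csf, flair = self.grids(shape)
        wm[0:2, :, 0] = 1.0
        gm[2:7, :, 0] = 1.0
        nvox = int((gm > 0.5).sum())
        flair[gm > 0.5] = np.linspace(90, 110, nvox)
        for r in (2, 3, 4):  # contiguous bright column reaching WM
            flair[r, 3, 0] = 200.0
        out = correct_wm_mask(make_volume(gm), make_volume(wm),
                              make_volume(csf), make_volume(flair))
        assert out.data[2, 3, 0] and out.data[3, 3, 0] and out.data[4, 3, 0]

    def test_empty_wm_rejected(self):
        shape = (5, 5, 1)
        gm, wm, csf, flair = self.grids(shape)
        gm[1:4, 1:4, 0] = 1.0
        flair[gm > 0.5] = 100.0
        with pytest.raises(ValueError, match="WM mask empty"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                correct_wm_mask(make_volume(gm), make_volume(wm),
                                make_volume(csf), make_volume(flair))


def candidate_mask(shape, coords):
    data = np.zeros(shape, dtype=bool)
    for c in coords:
        data[c] = True
    return make_mask(data)


class TestWMOverlapFilter:
    @pytest.mark.parametrize("inside,kept", [(6, True), (5, False), (10, True)])
    def test_strict_majority(self, inside, kept):
        shape = (1, 10, 1)
        cand = candidate_mask(shape, [(0, j, 0) for j in range(10)])
        wm = np.zeros(shape, dtype=bool)
        wm[0, :inside, 0] = True
        out = filter_by_wm_overlap(cand, make_mask(wm))
        assert out.data.any() == kept


class TestCorticalFilter:
    def fixture(self, region_size, touching):
        shape = (30, 30, 1)
        gm = np.zeros(shape)
        csf = np.zeros(shape)
        gm[:, 0:2, 0] = 1.0
        csf[:, 2:4, 0] = 1.0  # interface band around columns 1-3
        data = np.zeros(shape, dtype=bool)
        col = 3 if touching else 10  # col 3 is 4-adjacent to interface col 2
        n = 0
        for i in range(30):
            for j in range(col, 30):
                if n < region_size:
                    data[i, j, 0] = True
                    n += 1
            if n >= region_size:
                break
        return make_mask(data), make_volume(gm), make_volume(csf)

    def test_19_voxels_touching_removed(self):
        cand, gm, csf = self.fixture(19, touching=True)
        assert remove_cortical_false_positives(cand, gm, csf).count() == 0

    def test_20_voxels_touching_kept(self):
        cand, gm, csf = self.fixture(20, touching=True)
        assert remove_cortical_false_positives(cand, gm, csf).count() == 20

    def test_small_but_far_from_interface_kept(self):
        cand, gm, csf = self.fixture(10, touching=False)
        assert remove_cortical_false_positives(cand, gm, csf).count() == 10


class TestBrainstemFilter:
    def fixture(self, region_size, slice_index, on_msp, nz=4):
        shape = (20, 20, nz)
        data = np.zeros(shape, dtype=bool)
        x0 = 10 if on_msp else 0
        n = 0
        for i in range(x0, 20):
            for j in range(20):
                if n < region_size:
                    data[i, j, slice_index] = True
                    n += 1
            if n >= region_size:
                break
        msp = np.zeros(shape, dtype=bool)
        msp[10, :, :] = True
        return candidate_mask(shape, []), make_mask(data), make_mask(msp)

    def run(self, cand_mask, msp):
        return remove_brainstem_false_positives(
            cand_mask, msp, s_brainstem=50, lower_slice_fraction=0.5,
            affine=np.eye(4))

    def test_51_voxels_low_on_msp_removed(self):
        _, cand, msp = self.fixture(51, slice_index=0, on_msp=True)
        assert self.run(cand, msp).count() == 0

    def test_50_voxels_low_on_msp_kept(self):
        _, cand, msp = self.fixture(50, slice_index=0, on_msp=True)
        assert self.run(cand, msp).count() == 50

    def test_large_region_in_upper_slices_kept(self):
        _, cand, msp = self.fixture(200, slice_index=3, on_msp=True)
        assert self.run(cand, msp).count() == 200

    def test_large_low_region_off_msp_kept(self):
        _, cand, msp = self.fixture(60, slice_index=0, on_msp=False)
        assert self.run(cand, msp).count() == 60

    def test_missing_msp_skips_with_warning(self):
        _, cand, _ = self.fixture(60, slice_index=0, on_msp=True)
        with pytest.warns(UserWarning, match="mid-sagittal"):
            out = remove_brainstem_false_positives(cand, None)
        assert out.count() == 60

    def test_lower_slices_follow_affine_direction(self):
        flipped = np.diag([1.0, 1.0, -1.0, 1.0])  # slice 0 is superior
        flags = lower_slices(flipped, 4, 0.5)
        np.testing.assert_array_equal(flags, [False, False, True, True])
        flags = lower_slices(np.eye(4), 4, 0.5)
        np.testing.assert_array_equal(flags, [True, True, False, False])


@pytest.fixture(scope="module")
def lesion_case():
    """A 96x96x12 case with one 2 mL deep lesion, shared across the
    end-to-end tests below."""
    cfg = PhantomConfig(seed=11, n_lesions=1, lesion_volume_ml=2.0,
                        shape=(96, 96, 12))
    return generate_phantom(cfg)


class TestRunWhasa:
    def test_lesion_recovered_with_accurate_volume(self, lesion_case):
        c = lesion_case
        mask, report = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        true_ml = c.truth_mask.volume_ml()
        assert abs(report["wmh_volume_ml"] - true_ml) <= 0.2 * true_ml
        inter = (mask.data & c.truth_mask.data).sum()
        si = 2 * inter / (mask.count() + c.truth_mask.count())
        assert si >= 0.8
        assert report["t_wmh"] == pytest.approx(
            report["i_tilde"] + 2 * report["lambda"])

    def test_lesion_free_phantom_gives_empty_mask(self):
        cfg = PhantomConfig(seed=12, n_lesions=0, shape=(96, 96, 8))
        c = generate_phantom(cfg)
        mask, report = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        assert mask.count() == 0
        assert report["wmh_volume_ml"] == 0.0

    def test_cortical_artifact_removed(self):
        cfg = PhantomConfig(seed=13, n_lesions=1, lesion_volume_ml=1.5,
                            cortical_artifact=True, shape=(96, 96, 10))
        c = generate_phantom(cfg)
        art = c.anatomy["cortical_artifact"]
        assert art.any()
        mask, _ = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        assert not (mask.data & art).any()

    def test_determinism(self, lesion_case):
        c = lesion_case
        m1, r1 = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        m2, r2 = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert r1 == r2

    def test_filters_only_remove(self, lesion_case):
        c = lesion_case
        _, report = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
        stages = report["stages"]
        order = ["thresholded", "wm_overlap", "cortical_fp", "brainstem_fp"]
        voxels = [stages[s]["voxels"] for s in order]
        assert all(a >= b for a, b in zip(voxels, voxels[1:]))


class TestSelectionParams:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SelectionParams(wm_overlap_fraction=1.5)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            SelectionParams(s_fpmax=0)
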