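import numpy as np
import pytest
from scipy import ndimage

from hemidti import stats, wbss


class TestSmooth:
    def test_constant_preserved(self, small_phantom):
        mask = small_phantom.brain_mask
        img = np.full(mask.shape, 3.7)
        out = wbss.smooth(img, 8.0, (2, 2, 2.8), mask)
        assert np.abs(out[mask] - 3.7).max() < 1e-11

    def test_fwhm_zero_identity(self, rng):
        img = rng.normal(size=(8, 8, 8))
        out = wbss.smooth(img, 0.0, (2, 2, 2))
        assert np.array_equal(out, img)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError, match="fwhm"):
            wbss.smooth(np.zeros((4, 4, 4)), -1.0, (2, 2, 2))

    def test_impulse_closed_form(self):
        """Center of the impulse response equals the normalized Gaussian at 0."""
        vol = np.zeros((33, 33, 33))
        vol[16, 16, 16] = 1.0
        out = wbss.smooth(vol, 8.0, (2.0, 2.0, 2.0))
        sigma_vox = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        assert sigma_vox == pytest.approx(1.6986, abs=1e-4)
        expected = (1.0 / (sigma_vox * np.sqrt(2 * np.pi))) ** 3
        assert out[16, 16, 16] == pytest.approx(expected, rel=1e-6)

    def test_masked_mean_preserved(self, small_phantom, rng):
        mask = small_phantom.brain_mask
        img = rng.normal(0.5, 0.2, mask.shape)
        out = wbss.smooth(img, 8.0, (2, 2, 2.8), mask)
        assert out[mask].mean() == pytest.approx(img[mask].mean(), abs=1e-9)

    def test_no_bleed_outside_mask(self, small_phantom, rng):
        mask = small_phantom.brain_mask
        img = rng.uniform(0.2, 0.8, mask.shape)
        out = wbss.smooth(img, 8.0, (2, 2, 2.8), mask)
        assert np.all(out[~mask] == 0.0)


class TestVoxelwiseTest:
    def test_identical_groups_p_one(self, rng):
        maps = [rng.uniform(0.3, 0.7, (5, 5, 3)) for _ in range(3)]
        mask = np.ones((5, 5, 3), bool)
        p = wbss.voxelwise_test(maps, [m.copy() for m in maps], mask)
        assert np.all(p == 1.0)

    def test_outside_mask_p_one(self, rng):
        a = [rng.normal(0.5, 0.1, (4, 4, 4)) for _ in range(3)]
        b = [rng.normal(0.9, 0.1, (4, 4, 4)) for _ in range(3)]
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        p = wbss.voxelwise_test(a, b, mask)
        assert np.all(p[~mask] == 1.0)
        assert np.all(p[mask] <= 1.0)

    def test_consistency_with_scalar_test(self, rng):
        a = [rng.normal(0.5, 0.1, (3, 3, 2)) for _ in range(4)]
        b = [rng.normal(0.6, 0.1, (3, 3, 2)) for _ in range(4)]
        mask = np.ones((3, 3, 2), bool)
        p = wbss.voxelwise_test(a, b, mask)
        vox = (1, 2, 0)
        scalar = stats.mann_whitney([m[vox] for m in a], [m[vox] for m in b])
        assert p[vox] == pytest.approx(scalar.p_value, abs=1e-12)

    def test_effect_located_in_modified_hemisphere(self, rng):
        shape = (10, 8, 6)
        mask = np.ones(shape, bool)
        a = [rng.normal(0.5, 0.02, shape) for _ in range(5)]
        b = []
        for _ in range(5):
            m = rng.normal(0.5, 0.02, shape)
            m[:5] -= 0.2  # effect confined to the left half
            b.append(m)
        p = wbss.voxelwise_test(a, b, mask)
        assert np.unravel_index(np.argmin(p), shape)[0] < 5
        assert p[:5].mean() < p[5:].mean()

    def test_too_few_maps_rejected(self, rng):
        m = rng.normal(size=(3, 3, 3))
        with pytest.raises(ValueError, match="2 maps"):
            wbss.voxelwise_test([m], [m, m], np.ones((3, 3, 3), bool))

    def test_t_test_option(self, rng):
        a = [rng.normal(0.5, 0.1, (3, 3, 2)) for _ in range(4)]
        b = [rng.normal(0.7, 0.1, (3, 3, 2)) for _ in range(4)]
        mask = np.ones((3, 3, 2), bool)
        p = wbss.voxelwise_test(a, b, mask, test="t-test")
        from scipy.stats import ttest_ind
        vox = (0, 0, 0)
        ref = ttest_ind([m[vox] for m in a], [m[vox] for m in b]).pvalue
        assert p[vox] == pytest.approx(ref, abs=1e-12)


class TestFdr:
    def test_example(self):
        thr, sig = wbss.fdr_correct([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert list(sig) == [True, True, True, False]

    def test_all_ones_none(self):
        thr, sig = wbss.fdr_correct(np.ones(10), alpha=0.05)
        assert thr == 0.0
        assert not sig.any()

    def test_single_small_p(self):
        thr, sig = wbss.fdr_correct([0.04], alpha=0.05)
        assert sig.all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wbss.fdr_correct([], 0.05)

    def test_never_more_than_uncorrected(self, rng):
        p = rng.uniform(0, 1, 500)
        _, sig = wbss.fdr_correct(p, alpha=0.05)
        assert sig.sum() <= np.sum(p < 0.05)

    def test_brute_force_all_k(self, rng):
        """Check the step-up rule against explicit evaluation of every k."""
        for _ in range(20):
            p = np.sort(rng.uniform(0, 0.3, 12))
            alpha = 0.05
            thr, sig = wbss.fdr_correct(p, alpha)
            m = len(p)
            ks = [k for k in range(1, m + 1) if p[k - 1] <= k / m * alpha]
            if ks:
                expected_thr = p[max(ks) - 1]
                assert thr == pytest.approx(expected_thr)
                assert np.array_equal(sig, p <= expected_thr)
            else:
                assert not sig.any()


def _flood_fill_components(mask, connectivity):
    """Brute-force component labeling oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) \
                        and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(frozenset(comp))
    return set(comps)


class TestClusterFilter:
    def test_boundary_inclusive(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0:2, 0:2, 0:2] = True  # exactly 8 voxels
        kept, _, sizes, _ = wbss.cluster_filter(mask, min_cluster=8)
        assert kept.sum() == 8
        kept, _, _, _ = wbss.cluster_filter(mask, min_cluster=9)
        assert kept.sum() == 0

    def test_512_threshold(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[0:10, 0:10, 0:6] = True  # 600 voxels
        mask[12:17, 12:16, 12:17] = True  # 100 voxels
        kept, labels, sizes, _ = wbss.cluster_filter(mask, min_cluster=512)
        assert len(sizes) == 1
        assert list(sizes.values()) == [600]

    def test_peak_location(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        p = np.ones((8, 8, 8))
        p[4, 3, 5] = 1e-6
        _, _, _, peaks = wbss.cluster_filter(mask, 1, p_map=p)
        assert peaks[1] == (4, 3, 5)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_vs_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            mask = rng.uniform(size=(8, 8, 8)) < 0.3
            _, labels, _, _ = wbss.cluster_filter(mask, 1, connectivity)
            mine = set()
            for lab in np.unique(labels[labels > 0]):
                mine.add(frozenset(map(tuple, np.argwhere(labels == lab))))
            oracle = _flood_fill_components(mask, connectivity)
            assert mine == oracle


class TestRunWbss:
    def test_null_fdr_family_error_rate(self, rng):
        """Under the global null, reps with any FDR-significant voxel <= alpha
        plus binomial slack."""
        shape = (6, 6, 4)
        mask = np.ones(shape, bool)
        reps = 300
        alpha = 0.05
        hits = 0
        for _ in range(reps):
            a = [rng.normal(0.5, 0.05, shape) for _ in range(5)]
            b = [rng.normal(0.5, 0.05, shape) for _ in range(5)]
            # continuous p-values (t-test) make the check non-trivial: the
            # exact rank test's discrete support cannot reach BH's smallest
            # per-voxel criterion at this sample size
            p = wbss.voxelwise_test(a, b, mask, test="t-test")
            _, sig = wbss.fdr_correct(p[mask], alpha)
            hits += bool(sig.any())
        rate = hits / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert rate <= alpha + 2 * se

    def test_end_to_end_detects_effect(self, rng):
        shape = (12, 10, 6)
        mask = np.ones(shape, bool)
        a = [rng.normal(0.5, 0.01, shape) for _ in range(5)]
        b = []
        for _ in range(5):
            m = rng.normal(0.5, 0.01, shape)
            m[:6] -= 0.3
            b.append(m)
        cfg = wbss.WBSSConfig(fwhm=4.0, min_cluster=512)
        res = wbss.run_wbss(a, b, mask, (2, 2, 2.8), cfg)
        assert res.significant.any()
        assert res.significant[:6].sum() > res.significant[6:].sum()
        # scaled criterion applied at desk scale
        assert min(res.cluster_sizes.values()) >= wbss.scaled_min_cluster(shape)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            wbss.WBSSConfig(alpha=1.5)
        with pytest.raises(ValueError):
            wbss.WBSSConfig(connectivity=4)

    def test_scaled_min_cluster(self):
        assert wbss.scaled_min_cluster((128, 128, 64)) == 512
        assert wbss.scaled_min_cluster((48, 48, 24)) == round(
            512 * 48 * 48 * 24 / (128 * 128 * 64))
        assert wbss.scaled_min_cluster((4, 4, 4)) == 5
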